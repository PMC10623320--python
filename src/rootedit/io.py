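"""File formats: FASTA amplicons, trace matrices as TSV/JSON, spectra as
TSV. All round trips are lossless; malformed records raise with the line
number."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DNA_ALPHABET, Amplicon, IndelEvent, IndelSpectrum
from .simulate import TraceMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_amplicons",
    "write_amplicons",
    "read_trace",
    "write_trace",
    "read_spectra",
    "write_spectra",
]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: upper-case sequence}; non-ACGT raises."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(DNA_ALPHABET)
        if bad:
            raise ValueError(f"non-ACGT characters in record {rec.id!r}: {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_amplicons(path, amplicons: list[Amplicon]) -> None:
    """FASTA with the CDS bounds carried in the description (cds=start..end)."""
    records = [
        SeqRecord(
            Seq(a.sequence), id=a.id, description=f"cds={a.cds_start}..{a.cds_end}"
        )
        for a in amplicons
    ]
    SeqIO.write(records, str(path), "fasta")


def read_amplicons(path) -> list[Amplicon]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(maxsplit=1)
        tag = desc[1] if len(desc) > 1 else ""
        if not tag.startswith("cds="):
            raise ValueError(f"record {rec.id!r} lacks a cds=start..end tag")
        start_s, end_s = tag[4:].split("..")
        out.append(Amplicon(rec.id, str(rec.seq).upper(), int(start_s), int(end_s)))
    return out


def write_trace(path, trace: TraceMatrix) -> None:
    """Trace as TSV (pos, A, C, G, T) or JSON depending on the suffix."""
    path = Path(path)
    vals = trace.values
    if path.suffix == ".json":
        path.write_text(json.dumps({"signal": vals.tolist()}))
        return
    df = pd.DataFrame(vals, columns=list(DNA_ALPHABET))
    df.insert(0, "pos", np.arange(len(vals)))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trace(path) -> TraceMatrix:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return TraceMatrix(np.asarray(data["signal"], dtype=float))
    df = pd.read_csv(path, sep="\t")
    missing = {"pos", *DNA_ALPHABET} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    vals = df[list(DNA_ALPHABET)].to_numpy(dtype=float)
    try:
        return TraceMatrix(vals)
    except ValueError as exc:
        sums = vals.sum(axis=1)
        bad = int(np.argmax(np.abs(sums - 1.0) > 1e-6)) + 2  # header is line 1
        raise ValueError(f"{path}: invalid trace row at line {bad}: {exc}") from exc


def write_spectra(path, spectra: dict[str, IndelSpectrum]) -> None:
    """Spectra as TSV (root_id, size, inserted_bases, percentage, p_value);
    the wild-type share is carried as a size-0 row."""
    rows = []
    for root_id in sorted(spectra):
        spec = spectra[root_id]
        rows.append(
            {"root_id": root_id, "size": 0, "inserted_bases": "",
             "percentage": round(spec.wt_percentage, 4), "p_value": ""}
        )
        for e in sorted(spec, key=lambda e: (e.size, e.inserted_bases or "")):
            rows.append(
                {"root_id": root_id, "size": e.size,
                 "inserted_bases": e.inserted_bases or "",
                 "percentage": round(e.percentage, 4),
                 "p_value": "" if e.p_value is None else repr(e.p_value)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spectra(path) -> dict[str, IndelSpectrum]:
    df = pd.read_csv(path, sep="\t", dtype={"inserted_bases": str})
    out: dict[str, IndelSpectrum] = {}
    for root_id, sub in df.groupby("root_id", sort=False):
        events = []
        wt = 0.0
        for line_no, row in zip(sub.index + 2, sub.itertuples(index=False)):
            pct = float(row.percentage)
            if pct < 0:
                raise ValueError(f"{path}: negative percentage at line {line_no}")
            size = int(row.size)
            if size == 0:
                wt = pct
                continue
            bases = row.inserted_bases if isinstance(row.inserted_bases, str) else ""
            pval = None if pd.isna(row.p_value) else float(row.p_value)
            events.append(
                IndelEvent(
                    size=size, percentage=pct,
                    inserted_bases=bases or None, p_value=pval,
                )
            )
        out[str(root_id)] = IndelSpectrum(events=events, wt_percentage=wt)
    return out
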