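# Pooled indel-size distribution fixture for the synthetic repair-outcome
# generator. Support: deletions -30..-1 bp, insertions +1..+4 bp.
# Anchored values: P(-1)=0.226 and P(+1)=0.191 (the pooled 1-bp deletion and
# insertion frequencies of the study cohort); total deletion mass 0.75 and
# insertion mass 0.25 (the observed ~3:1 deletion:insertion ratio). The
# remaining deletion mass is spread geometrically (ratio 0.82) over -2..-30
# and the remaining insertion mass geometrically (ratio 0.5) over +2..+4 --
# a modeling choice: only the two 1-bp frequencies and the support bounds are
# observed, the tail shape is not.
size	weight
-30	0.000365400473
-29	0.000445610333
-28	0.000543427235
-27	0.000662716140
-26	0.000808190415
-25	0.000985598067
-24	0.001201948862
-23	0.001465791295
-22	0.001787550359
-21	0.002179939463
-20	0.002658462759
-19	0.003242027755
-18	0.003953692385
-17	0.004821576079
-16	0.005879970828
-15	0.007170696131
-14	0.008744751380
-13	0.010664330951
-12	0.013005281648
-11	0.015860099570
-10	0.019341584842
-9	0.023587298588
-8	0.028764998277
-7	0.035079266192
-6	0.042779592917
-5	0.052170235265
-4	0.063622238128
-3	0.077588095278
-2	0.094619628388
-1	0.226000000000
1	0.191000000000
2	0.033714285714
3	0.016857142857
4	0.008428571429
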