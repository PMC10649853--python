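# Single-dose biomarker hit counts per compound and tested concentration,
# transcribed from the reference study's hit-count table (the raw per-biomarker
# profiles behind these counts live in an appendix that is not reproduced, so
# the counts are inputs to the optimal-dose rule, not recomputed here).
# columns: compound	dose_uM	hits
compound	dose_uM	hits
C15:0	1.9	28
C15:0	5.6	56
C15:0	17	81
C15:0	50	40
rapamycin	0.3	55
rapamycin	1	62
rapamycin	3	61
rapamycin	9	75
metformin	190	9
metformin	560	5
metformin	1700	28
metformin	5000	53
acarbose	1.1	15
acarbose	3.3	17
acarbose	10	24
acarbose	30	28
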