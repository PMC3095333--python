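# Demonstration subset of named plant cis-element words (IUPAC patterns).
# Supply a full motif table with `--motifs` for real analyses.
CAATBOX1	CCAAT
TATABOX5	TTATTT
GATABOX	GATAG
IBOXCORE	GATAA
DOFCOREZM	AAAGC
CACGTGMOTIF	CACGTG
EBOXBNNAPA	CANNTG
MYBCORE	CNGTTR
WBOXNTERF3	TGACY
GT1CONSENSUS	GRWAAW
ARR1AT	NGATT
POLLEN1LELAT52	AGAAA
CURECORECR	GTAC
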