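# Synthetic stand-in list of essential Pfam-A domain accessions (102 entries).
#
# Default universal single-copy marker-domain panel used by the essential-gene
# component score: domains expected in nearly every finished bacterial and
# archaeal genome (ribosomal proteins, translation factors, aminoacyl-tRNA
# synthetase classes, RNA polymerase subunits, core replication and secretion
# machinery). This file is a synthetic reconstruction assembled from broadly
# conserved prokaryotic families; it is NOT a published reference panel.
# Replace it with your own accession list via ScoringConfig / --config to
# score against a different marker set. One accession per line; '#' comments
# and blank lines ignored; version suffixes (PF00312.14) are stripped on load.
PF00687
PF00181
PF00297
PF00573
PF00281
PF00347
PF03948
PF01281
PF00466
PF00298
PF03946
PF00542
PF00572
PF00238
PF00252
PF01196
PF00861
PF01245
PF00453
PF00829
PF00237
PF00276
PF01386
PF01016
PF00830
PF00831
PF00327
PF01197
PF01783
PF00471
PF00468
PF01632
PF00444
PF00318
PF00189
PF00163
PF00333
PF01250
PF00177
PF00410
PF00380
PF00338
PF00411
PF00164
PF00416
PF00253
PF00312
PF00886
PF00366
PF01084
PF00203
PF01649
PF00009
PF03144
PF00679
PF00133
PF00749
PF00750
PF00152
PF00587
PF01409
PF02403
PF01000
PF00562
PF00623
PF01193
PF01192
PF00344
PF00584
PF00448
PF02881
PF00012
PF00118
PF01018
PF01176
PF04760
PF00707
PF05198
PF00154
PF00204
PF00521
PF02767
PF02768
PF01807
PF00308
PF01765
PF00557
PF01327
PF01668
PF00825
PF00113
PF00162
PF00406
PF01715
PF01746
PF00588
PF03119
PF01653
PF02978
PF00763
PF01795
PF00889
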