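#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
protB                -            138 toydom               -             50   4.1e-38  117.0   7.7   1   2   4.1e-38   4.1e-38  117.0   7.7     1    50     1    50     1    50 1.00 second toy protein
protB                -            138 toydom               -             50   4.1e-38  117.0   7.7   2   2      0.31      0.31   -1.0   0.2    13    30    75    92    73    97 0.75 second toy protein
protA                -            138 toydom               -             50   9.7e-38  115.8   8.5   1   2   9.7e-38   9.7e-38  115.8   8.5     1    50     1    50     1    50 1.00 first toy protein
protA                -            138 toydom               -             50   9.7e-38  115.8   8.5   2   2       1.1       1.1   -2.8   0.2    14    29    76    91    71    96 0.63 first toy protein
protC                -            152 toydom               -             50   7.6e-24   71.3   2.6   1   2   7.6e-24   7.6e-24   71.3   2.6     7    50    20    64    17    64 0.97 third toy protein
protC                -            152 toydom               -             50   7.6e-24   71.3   2.6   2   2      0.24      0.24   -0.7   0.2    13    30    89   106    83   112 0.75 third toy protein
#
# Program:         hmmsearch
# Version:         3.4 (Aug 2023)
# Pipeline mode:   SEARCH
# Query file:      toydom.hmm
# Target file:     toy.fa
# Option settings: hmmsearch --domtblout real_hmmsearch.domtblout toydom.hmm toy.fa 
# Current dir:     /root/pkg/scratch
# Date:            Sat Sep  5 20:04:32 2026
# [ok]
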