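# Function labels already reported in marine viromes (one per line).
# Candidate novel genes must NOT match any of these (nor any structural
# or marker family). Edit freely: the pipeline treats this file as data.
psbA
psbD
hli
phoH
pstS
mazG
talC
transaldolase
speD
cobS
nrdA
nrdB
thyX
cp12
petE
petF
purH
dut
folE
prnA
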