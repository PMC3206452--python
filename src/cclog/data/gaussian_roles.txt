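# Restructuring rules for the Gaussian template pack.
# templateId = jobstart | environment | initialization | calculation |
#              finalization | molecule | drop
l1.link1=jobstart
l1.banner=environment
l101.route=initialization
l101.chargemult=initialization
l101.natoms=initialization
l202.orient=molecule
l202.pg=initialization
l301.basis=initialization
l301.nucrep=calculation
l502.scf=finalization
l601.alphabetaeigen=finalization
l716.freq=finalization
l716.thermo=finalization
l9999.term=drop
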