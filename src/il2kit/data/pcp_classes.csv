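class,residues
positively_charged,KRH
negatively_charged,DE
neutral,ACFGILMNPQSTVWY
charged,DEHKR
polar,DEHKNQRSTY
nonpolar,ACFGILMPVW
aliphatic,AGILV
aromatic,FHWY
cyclic,P
tiny,ACGST
small,ACDGNPSTV
large,EFHIKLMQRWY
hydrophobic,ACFGILMVWY
hydrophilic,DEKNQR
sulfur_containing,CM
hydroxyl_containing,ST
amide_containing,NQ
helix_favoring,AEHKLMQR
strand_favoring,CFITVWY
coil_favoring,DGNPS
buried,ACFGILVW
exposed,DEKNQR
intermediate_accessibility,HMPSTY
low_vdw_volume,ACDGPST
medium_vdw_volume,EILNQV
high_vdw_volume,FHKMRWY
low_polarity,CFILMVWY
medium_polarity,AGPST
high_polarity,DEHKNQR
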