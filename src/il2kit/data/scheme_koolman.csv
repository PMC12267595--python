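group,residues
aliphatic,AVLIG
aromatic,FWYH
sulfur,CM
hydroxyl,ST
basic,KRH
acidic_amide,DENQ
imino,P
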