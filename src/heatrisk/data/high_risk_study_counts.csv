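species_id,n_studies
Dasyuroides byrnei,5
Lasiorhinus krefftii,3
Notomys cervinus,1
Rhinonicteris aurantia,1
Zyzomys pedunculatus,1
Notomys fuscus,0
Sminthopsis douglasi,0
Petrogale purpureicollis,0
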