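species_id,risk,n_sites
Dasyuroides byrnei,high,1
Lasiorhinus krefftii,high,1
Sminthopsis douglasi,high,1
Zyzomys pedunculatus,high,1
Notomys cervinus,high,0
Notomys fuscus,high,0
Petrogale purpureicollis,high,0
Rhinonicteris aurantia,high,0
Bettongia lesueur,moderate,11
Dasycercus cristicauda,moderate,1
Lagorchestes hirsutus,moderate,5
Lagostrophus fasciatus,moderate,4
Leporillus conditor,moderate,7
Myrmecobius fasciatus,moderate,5
Onychogalea fraenata,moderate,2
Perameles bougainville,moderate,5
Pseudomys gouldii,moderate,3
Trichosurus vulpecula,moderate,3
Pseudantechinus mimulus,moderate,0
Sminthopsis psammophila,moderate,0
Bettongia penicillata,low,11
Dasyurus geoffroii,low,7
Dasyurus hallucatus,low,2
Isoodon auratus,low,7
Lagorchestes conspicillatus,low,1
Lasiorhinus latifrons,low,1
Macrotis lagotis,low,13
Petrogale lateralis,low,7
Phascogale calura,low,6
Phascolarctos cinereus,low,6
Pseudomys australis,low,2
Chalinolobus picatus,low,0
Macroderma gigas,low,0
Petrogale xanthopus,low,0
Pseudomys occidentalis,low,0
Setirostris eleryi,low,0
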