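species_id,common_name,order,iucn,mass_g,decline_pct,risk
Dasyuroides byrnei,Kowari,Da,VUL,109,86.1,high
Lasiorhinus krefftii,Northern hairy-nosed wombat,Di,CE,31900,99.9,high
Notomys cervinus,Fawn hopping mouse,Ro,NT,35,97.0,high
Notomys fuscus,Dusky hopping mouse,Ro,VUL,39,88.9,high
Petrogale purpureicollis,Purple-necked rock-wallaby,Di,NT,4500,81.1,high
Rhinonicteris aurantia,Orange leaf-nosed bat,Ch,LC,9,,high
Sminthopsis douglasi,Julia Creek dunnart,Da,NT,55,57.0,high
Zyzomys pedunculatus,Central rock rat,Ro,CE,100,98.2,high
Bettongia lesueur,Boodie,Di,VUL,1400,99.9,moderate
Dasycercus cristicauda,Ampurta,Da,NT,100,90.0,moderate
Lagorchestes hirsutus,Rufous hare-wallaby,Di,VUL,1400,99.9,moderate
Lagostrophus fasciatus,Banded hare-wallaby,Di,VUL,1900,99.9,moderate
Leporillus conditor,Greater stick-nest rat,Ro,NT,329,99.9,moderate
Myrmecobius fasciatus,Numbat,Da,END,511,99.9,moderate
Onychogalea fraenata,Bridled nailtail wallaby,Di,VUL,5000,99.9,moderate
Perameles bougainville,Shark Bay bandicoot,Pe,VUL,231,99.9,moderate
Pseudantechinus mimulus,Carpentarian pseudantechinus,Da,NT,17,87.1,moderate
Pseudomys gouldii,Shark Bay mouse,Ro,VUL,42,99.9,moderate
Sminthopsis psammophila,Sandhill dunnart,Da,VUL,34,90.1,moderate
Trichosurus vulpecula,Brushtail possum,Di,LC,2700,,moderate
Bettongia penicillata,Woylie,Di,CE,1200,99.9,low
Chalinolobus picatus,Little pied wattled bat,Ch,NT,6,44.5,low
Dasyurus geoffroii,Western quoll,Da,NT,1100,94.6,low
Dasyurus hallucatus,Northern quoll,Da,END,471,81.9,low
Isoodon auratus,Golden bandicoot,Pe,VUL,425,98.4,low
Lagorchestes conspicillatus,Spectacled hare-wallaby,Di,LC,2800,33.2,low
Lasiorhinus latifrons,Southern hairy-nosed wombat,Di,NT,26200,74.4,low
Macroderma gigas,Ghost bat,Ch,VUL,124,76.0,low
Macrotis lagotis,Greater bilby,Pe,VUL,1200,75.5,low
Petrogale lateralis,Black-flanked rock-wallaby,Di,VUL,4600,79.6,low
Petrogale xanthopus,Yellow-footed rock wallaby,Di,NT,8500,85.2,low
Phascogale calura,Red-tailed phascogale,Da,NT,43,98.8,low
Phascolarctos cinereus,Koala,Di,VUL,6500,41.1,low
Pseudomys australis,Plains mouse,Ro,VUL,53,82.7,low
Pseudomys occidentalis,Western mouse,Ro,NT,34,76.5,low
Setirostris eleryi,Bristle-faced freetail bat,Ch,NT,7,80.0,low
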