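family	genus	exemplar_species
Buthidae	Afroisometrus	1
Buthidae	Alayotityus	1
Buthidae	Babycurus	1
Buthidae	Butheolus	1
Buthidae	Buthoscorpio	2
Buthidae	Buthus	1
Buthidae	Centruroides	1
Buthidae	Cicileus	1
Buthidae	Grosphus	1
Buthidae	Isometroides	1
Buthidae	Isometrus	2
Buthidae	Karasbergia	1
Buthidae	Lychas	2
Buthidae	Microbuthus	1
Buthidae	Neobuthus	1
Buthidae	Neogrosphus	1
Buthidae	Odonturus	1
Buthidae	Orthochirus	1
Buthidae	Parabuthus	1
Buthidae	Physoctonus	1
Buthidae	Pseudolychas	1
Buthidae	Rhopalurus	1
Buthidae	Sassanidotus	1
Buthidae	Thaicharmus	1
Buthidae	Tityopsis	1
Buthidae	Uroplectes	1
Buthidae	Zabius	1
Chactidae	Nullibrotheas	1
Chaerilidae	Chaerilus	10
Iuridae	Caraboctonus	1
Iuridae	Hadruroides	1
Iuridae	Hadrurus	1
Iuridae	Hoffmannihadrurus	2
Troglotayosicidae	Troglotayosicus	1
Vaejovidae	Franckeus	1
Vaejovidae	Gertschius	1
Vaejovidae	Kochius	1
Vaejovidae	Maaykuyak	1
Vaejovidae	Mesomexovis	1
Vaejovidae	Paruroctonus	1
Vaejovidae	Pseudouroctonus	1
Vaejovidae	Serradigitus	1
Vaejovidae	Stahnkeus	1
Vaejovidae	Syntropis	1
Vaejovidae	Thorellius	1
Vaejovidae	Vaejovis	2
Total	Total	60
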