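family	species	median	lateral
Akravidae	Akrav israchanani	abs.	abs.
Chaerilidae	Chaerilus sabinae	abs.	abs.
Chaerilidae	Chaerilus telnovi	abs.	pres.
Diplocentridae	Diplocentrus actan	abs.	pres.
Diplocentridae	Diplocentrus anophthalmus	abs.	pres.
Hormuridae	Hormurus polisorum	abs./pres.	pres.
Pseudochactidae	Vietbocap canhi	abs.	abs.
Pseudochactidae	Vietbocap lao	abs.	abs.
Pseudochactidae	Vietbocap thienduongensis	abs.	abs.
Euscorpiidae	Troglocormus ciego	abs.	pres.
Euscorpiidae	Troglocormus willis	abs.	pres.
Troglotayosicidae	Belisarius xambeui	abs.	abs.
Troglotayosicidae	Troglotayosicus hirsutus	abs.	pres.
Troglotayosicidae	Troglotayosicus humiculum	abs.	pres.
Troglotayosicidae	Troglotayosicus vachoni	abs.	pres.
Typhlochactidae	Alacran chamuco	abs.	abs.
Typhlochactidae	Alacran tartarus	abs.	abs.
Typhlochactidae	Sotanochactas elliotti	abs.	abs.
Typhlochactidae	Stygochactas granulosus	abs.	abs.
Typhlochactidae	Typhlochactas cavicola	abs.	abs.
Typhlochactidae	Typhlochactas mitchelli	abs.	abs.
Typhlochactidae	Typhlochactas reddelli	abs.	abs.
Typhlochactidae	Typhlochactas rhodesi	abs.	abs.
Typhlochactidae	Typhlochactas sissomi	abs.	abs.
Typhlochactidae	Typhlochactas sylvestris	abs.	abs.
Urodacidae	Aops oncodactylus	abs.	abs.
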