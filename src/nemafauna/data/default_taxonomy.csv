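genus,guild,cp_value
Acrobeles,Ba,2
Acrobeloides,Ba,2
Acrolobus,Ba,2
Aphelenchus,Fu,2
Boleodorus,Pp,2
Cephalobus,Ba,2
Cervidellus,Ba,2
Criconema,Pp,3
Discolaimium,Op,5
Ditylenchus,Fu,2
Eucephalobus,Ba,2
Eudorylaimus,Op,4
Filenchus,Pp,2
Helicotylenchus,Pp,3
Hemicriconemoides,Pp,3
Hemicycliophora,Pp,3
Heterodera,Pp,3
Heterodorus,Op,4
Iotonchus,Op,4
Kirjiahovia,Ba,2
Labronemella,Op,4
Lelenchus,Pp,2
Malenchus,Pp,2
Mesodorylaimus,Op,4
Panagrellus,Ba,1
Panagrobelus,Ba,1
Paraphelenchus,Fu,2
Pseudacrobeles,Ba,2
Rhabditis,Ba,1
Rhabditonema,Ba,1
Rotylenchus,Pp,3
Scutellonema,Pp,3
Stegelleta,Ba,2
Tylenchus,Pp,2
Wilsonema,Ba,2
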