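((((((((((((((((sp01_amar:1.0,sp02_amar:1.0):0.5,sp03_amar:1.0)Amaranthaceae:1.0,((sp04_tama:1.0,sp05_tama:1.0):0.5,sp06_tama:1.0)Tamaricaceae:1.0):0.5,((sp07_zygo:1.0,sp08_zygo:1.0):0.5,sp09_zygo:1.0)Zygophyllaceae:1.0):0.5,((sp10_nitr:1.0,sp11_nitr:1.0):0.5,sp12_nitr:1.0)Nitrariaceae:1.0):0.5,((sp13_faba:1.0,sp14_faba:1.0):0.5,sp15_faba:1.0)Fabaceae:1.0):0.5,((sp16_aste:1.0,sp17_aste:1.0):0.5,sp18_aste:1.0)Asteraceae:1.0):0.5,(sp19_poac:1.0,sp20_poac:1.0)Poaceae:1.0):0.5,(sp21_plum:1.0,sp22_plum:1.0)Plumbaginaceae:1.0):0.5,(sp23_poly:1.0,sp24_poly:1.0)Polygonaceae:1.0):0.5,(sp25_bras:1.0,sp26_bras:1.0)Brassicaceae:1.0):0.5,(sp27_sola:1.0,sp28_sola:1.0)Solanaceae:1.0):0.5,(sp29_elae:1.0,sp30_elae:1.0)Elaeagnaceae:1.0):0.5,(sp31_ephe:1.0,sp32_ephe:1.0)Ephedraceae:1.0):0.5,(sp33_rosa:1.0,sp34_rosa:1.0)Rosaceae:1.0):0.5,(sp35_apoc:1.0,sp36_apoc:1.0)Apocynaceae:1.0);
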