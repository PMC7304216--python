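11
Tigray
2
1 5
Afar
3
0 2 10
Amhara
4
1 5 6 9
Oromia
2
6 9
Somali
2
8 9
Benishangul
3
0 2 7
SNNPR
3
2 3 7
Gambela
2
5 6
Harari
2
4 10
Addis Ababa
4
2 3 4 10
Dire Dawa
3
1 8 9
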