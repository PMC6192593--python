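roost,1,2,3,4,5,6,7,8,9,10,11,12
1,885,1207,1001,729,1201,2896,2287,796,505,940,447,593
2,497,285,282,228,258,915,869,562,309,524,653,460
3,318,112,191,286,119,422,826,385,645,855,470,287
4,281,279,365,559,752,1063,815,385,451,471,261,313
5,310,188,38,32,103,147,110,168,100,202,200,24
pooled,2726,2156,1860,1979,2232,5288,4640,1950,2011,3065,2155,1722
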