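rhythm_id,click_count,s1,s2,s3,s4,s5,s6,s7,s8,s9
10c1,10,0.1111111111111111,0.1111111111111111,0.1111111111111111,0.1111111111111111,0.1111111111111111,0.1111111111111111,0.1111111111111111,0.1111111111111111,0.1111111111111111
3c1,3,0.5,0.5,,,,,,,
4c1,4,0.3333333333333333,0.3333333333333333,0.3333333333333333,,,,,,
4c2,4,0.5,0.25,0.25,,,,,,
5c1,5,0.25,0.25,0.25,0.25,,,,,
5c2,5,0.4,0.2,0.2,0.2,,,,,
5c3,5,0.18181818181818182,0.18181818181818182,0.45454545454545453,0.18181818181818182,,,,,
6c1,6,0.2,0.2,0.2,0.2,0.2,,,,
6c2,6,0.3333333333333333,0.16666666666666666,0.16666666666666666,0.16666666666666666,0.16666666666666666,,,,
6c3,6,0.15384615384615385,0.15384615384615385,0.38461538461538464,0.15384615384615385,0.15384615384615385,,,,
7c1,7,0.16666666666666666,0.16666666666666666,0.16666666666666666,0.16666666666666666,0.16666666666666666,0.16666666666666666,,,
7c2,7,0.2222222222222222,0.2,0.17777777777777778,0.15555555555555556,0.13333333333333333,0.1111111111111111,,,
7c3,7,0.13333333333333333,0.13333333333333333,0.13333333333333333,0.3333333333333333,0.13333333333333333,0.13333333333333333,,,
8c1,8,0.14285714285714285,0.14285714285714285,0.14285714285714285,0.14285714285714285,0.14285714285714285,0.14285714285714285,0.14285714285714285,,
8c2,8,0.125,0.125,0.125,0.125,0.125,0.125,0.25,,
8c3,8,0.11764705882352941,0.11764705882352941,0.11764705882352941,0.29411764705882354,0.11764705882352941,0.11764705882352941,0.11764705882352941,,
9c1,9,0.125,0.125,0.125,0.125,0.125,0.125,0.125,0.125,
9c2,9,0.16666666666666666,0.15476190476190477,0.14285714285714288,0.13095238095238096,0.11904761904761905,0.10714285714285715,0.09523809523809523,0.08333333333333333,
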