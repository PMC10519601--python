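name,level1,level2,level3,level4,is_mh,is_bd
bipolar,health,mental health,mood disorders,bipolar,1,1
bipolarreddit,health,mental health,mood disorders,bipolar,1,1
bipolar2,health,mental health,mood disorders,bipolar,1,1
bipolarsos,health,mental health,mood disorders,bipolar,1,1
mentalhealth,health,mental health,general,,1,0
depression,health,mental health,mood disorders,depression,1,0
anxiety,health,mental health,anxiety disorders,,1,0
suicidewatch,health,mental health,crisis support,,1,0
mentalillness,health,mental health,general,,1,0
askreddit,discussion,general,,,0,0
gaming,entertainment,games,video games,,0,0
movies,entertainment,film,,,0,0
science,education,science,,,0,0
funny,entertainment,humour,,,0,0
music,entertainment,music,,,0,0
books,entertainment,literature,,,0,0
aww,entertainment,animals,,,0,0
personalfinance,lifestyle,finance,,,0,0
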