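# Published road-effect-zone distances (metres) at six activity-decline
# thresholds for the central Victoria freeway bat surveys; empty cells mean
# no zone at that threshold.
species,50%,30%,25%,20%,15%,10%
Austronomus australis,,,,,,18
Chalinolobus gouldii,,23,55,123,263,538
Chalinolobus morio,61,333,471,652,884,1178
Nyctophilus-Myotis complex,25,215,331,496,724,1035
Ozimops ridei,,,,,,
Ozimops planiceps,,,,,,
Scotorepens balstoni,17,178,285,441,665,980
Vespadelus darlingtoni,14,159,260,411,632,948
Vespadelus regulus,161,548,704,890,1109,1365
Vespadelus vulturnus,41,274,403,577,809,1112
all species combined,5,99,178,307,511,826
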