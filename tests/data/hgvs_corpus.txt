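# Golden corpus of clinically reported CNV nomenclature strings
# (whitespace-normalized; obvious transcription defects repaired: MLH1
# 117-21 hyphen restored, dup suffixes completed on the ATM four-copy and
# the first BRCA1 duplication entry).
# The APC entry is base-resolved (breakpoint-sequenced) and is parse-only.
MSH2:c.(?_-21)_(*21_?)del
MSH6:c.(?_-21)_(*21_?)del
MLH1:c.(116+21_117-21)_(545+21_546-21)del
PMS2:c.(537+21_538-21)_(903+21_904-21)del
BRCA2:c.(?_-21)_(67+21_68-21)del
ATM:c.(8850+21_8851-21)_(*21_?)dup
PALB2:c.(2586+21_2587-21)_(2748+21_2749-21)del
BRCA1:c.(5406+21_5407-21)_(*21_?)del
BRCA1:c.(5332+21_5333-21)_(5406+21_5407-21)del
BRCA1:c.(4357+21_4358-21)_(4484+21_4485-21)del
BRCA1:c.(?_-21)_(80+21_81-21)dup
RAD51C:c.(571+21_572-21)_(*21_?)del
CHEK2:c.(908+21_909-21)_(1095+21_1096-21)del
CHEK2:c.(319+21_320-21)_(592+21_593-21)dup
MSH2:c.(366+21_367-21)_(1076+21_1077-21)del
MSH6:c.(?_-21)_(260+21_261-21)del
BARD1:c.(?_-21)_(*21_?)del
APC:c.1958+241_4457del
PMS2:c.(2006+21_2007-21)_(*21_?)dup
ATM:c.(662+21_663-21)_(9171+21_9172-21)dup
BRCA2:c.(8487+21_8488-21)_(8632+21_8633-21)del
RAD51D:c.(?_-21)_(*21_?)del
BRCA1:c.(5277+21_5278-21)_(*21_?)del
BRCA1:c.(4986+21_4987-21)_(5074+21_5075-21)del
BRCA1:c.(4185+21_4186-21)_(4357+21_4358-21)dup
BRCA1:c.(?_-21)_(80+21_81-21)del
RAD51C:c.(837+21_838-21)_(965+21_966-21)dup
CHEK2:c.(1461+21_1462-21)_(*21_?)del
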