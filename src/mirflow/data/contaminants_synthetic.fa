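>rRNA-synthetic-1 class=rRNA
CCCUCCACGGGACAAAGCAUCUAUGCGGACGUCUAGGACGCGUAACUUUUGCCCGCAGGAUGCAGUGCGCCGUUGAGCACCGCGUUGGCCA
>rRNA-synthetic-2 class=rRNA
ACCAGUAUCUCAGGGAACAGUUAUGCCCCCUAUGAAAUGAAACCUUAGCAGAGGUGUAACGACAGCUUUGAGCGGAGUCUGUCACGGUCGAGUUCCGCGGGGGCCAACC
>rRNA-synthetic-3 class=rRNA
UAUCGCAAUACGUUCAAAUGAUAAGCGCGCAUUGAUAAUAGCAGGUGCUUAUCUGUCUGCGGCCUCGCCUUCUAUGGCCACGCCGUAAAUUCCCAGUUCAUUGGAUCACGAAUUGUAGGUAAAUGUGUC
>rRNA-synthetic-4 class=rRNA
ACCGCUUUUGAAGAUUCCGUUGCAAAACAAUCGUUUAACAGGGCGCGGCACGAUGGGUCCCACUAGCGUUACUCCGCGAAUUAUGGCCGCUGGAUCGGAGUCCUAGGCUAUCC
>tRNA-synthetic-1 class=tRNA
AUGAAACGCACAUACACUAGUACACCUCACUGACCUCUAUAUAUGCCUGCAGUAGACACGCUGCCAUGAGUGCA
>tRNA-synthetic-2 class=tRNA
GGUAUCAGAUGUGCAAUGGCUAGCAACAAGACCGUGAUUGCGCGCAACUACUGCUACGCUUCUAAGGAUGCAAAGGGCAGUUACAGUCCUAGUC
>tRNA-synthetic-3 class=tRNA
GAGCCACAAUCUGCCACCGUUCCCAAAAAUAACGGUGGGGGUAUCUCUUCAAUCACAUUCGAUCAAGCUAUGUAUCAAAGGGGAAGAUCCUCCUUAAUGACCCUGACC
>tRNA-synthetic-4 class=tRNA
GAACGCUGAUUGUCCGCAACCCGAAUCAGUAUGACAUGCUACCCUGUGGUGAUGGGAAGAAAUACGCCAUGAUCUGCCAGACGGGUCUGCUGAUUCUUAUUUUAUAGCCCUAGUCCUAGUU
>tRNA-synthetic-5 class=tRNA
CUAUCAGAUGUGGCUGGGUGUAAUACUUCUCUUAGGCAGUGAAGAAUGGUACCCCUCAGGCGAUUAAGAGACCCACGGGAUCU
>snoRNA-synthetic-1 class=snoRNA
ACGCGGCAUAAGCGACAUUGCGCCCACCCAUUGUGUGAUCGACCGACGAUAGUCACAGGUCAUCAAUCUGCGCGGUAGAGCAUUUCAUAAUAUUUGACUAAGUUAAUGCGCUCAUAACGCGCCCCCCU
>snoRNA-synthetic-2 class=snoRNA
UCGACGCGAGACAUCUGGUCCUAGCAUCCGGCAUUUAUUUGGAAUAUAAGGUGCUAGUGAGCG
>snoRNA-synthetic-3 class=snoRNA
AUUUUGAUACAGCCUCCGAUUAGCGUUUACCGCUGGAUCCCGCAUGGCACACCACGCUUGCUCCCAUGCCCACUACAUCAGGAGCCAGCUCACUGUCAUAGCCACAAAGCGAGUACUGCCUU
>snRNA-synthetic-1 class=snRNA
AUGGAAUACUUAUACUGAACGUGAGCUACCGGUCCCGAUGGGGCUCCACGAUCGGUCCCGAUCAGAGUUCCUUCGAUAGUAACUGUACUGGUUAUUGGUAGGGGAAACUAC
>snRNA-synthetic-2 class=snRNA
UGAGUAACUAGAACGAUUGUACUAAGACCCCAGGCCACGUCGAAGUUUCGUGAACCCGAAGUGGGUUGGGACUGCUUAGAUUCGA
>snRNA-synthetic-3 class=snRNA
CUAAGGGCCAUGACCUAUCAUCUUUACCAUUAUCGUGUAUCCGGCCGCGGGAAUUACUAG
>YRNA-synthetic-1 class=YRNA
AUAAAGCUUUCCUAUGAGAGUUCUUAAAAAUGGAAUACAUUAGCAGUGAGUAAAAUACGUCGAACCUUUUCUCCCUUGACUGUGUU
>YRNA-synthetic-2 class=YRNA
GUCCUUACGUGUAGUUCCGGACCUCUCCCACUCGACAGGUCAGUACGAAUCGGAUUGUCUCCGGGAGAUCUUAUCUAAGCUGUUCUGUACCCCGUAGAACGGGUUAUACUCACGUUGUAUAG
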