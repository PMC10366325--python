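>hsa-miR-367-3p
AAUUGCACUUUAGCAAUGGUGA
>hsa-miR-302d-3p
UAAGUGCUUCCAUGUUUGAGUGU
>hsa-miR-302a-3p
UAAGUGCUUCCAUGUUUUGGUGA
>hsa-miR-302c-3p
UAAGUGCUUCCAUGUUUCAGUGG
>hsa-miR-302b-3p
UAAGUGCUUCCAUGUUUUAGUAG
>hsa-miR-17-5p
CAAAGUGCUUACAGUGCAGGUAG
>hsa-miR-18a-5p
UAAGGUGCAUCUAGUGCAGAUAG
>hsa-miR-19a-3p
UGUGCAAAUCUAUGCAAAACUGA
>hsa-miR-20a-5p
UAAAGUGCUUAUAGUGCAGGUAG
>hsa-miR-19b-3p
UGUGCAAAUCCAUGCAAAACUGA
>hsa-miR-92a-3p
UAUUGCACUUGUCCCGGCCUGU
>hsa-miR-363-3p
AAUUGCACGGUAUCCAUCUGUA
>hsa-miR-20b-5p
CAAAGUGCUCAUAGUGCAGGUAG
>hsa-miR-18b-5p
UAAGGUGCAUCUAGUGCAGUUAG
>hsa-miR-106a-5p
AAAAGUGCUUACAGUGCAGGUAG
>hsa-miR-25-3p
CAUUGCACUUGUCUCGGUCUGA
>hsa-miR-93-5p
CAAAGUGCUGUUCGUGCAGGUAG
>hsa-miR-106b-5p
UAAAGUGCUGACAGUGCAGAU
>hsa-miR-9-5p
UCUUUGGUUAUCUAGCUGUAUGA
>hsa-miR-124-3p
UAAGGCACGCGGUGAAUGCC
>hsa-miR-181a-5p
AACAUUCAACGCUGUCGGUGAGU
>hsa-miR-30a-5p
UGUAAACAUCCUCGACUGGAAG
>hsa-let-7a-5p
UGAGGUAGUAGGUUGUAUAGUU
>hsa-miR-200c-3p
UAAUACUGCCGGGUAAUGAUGGA
>hsa-miR-219a-5p
UGAUUGUCCAAACGCAAUUCU
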