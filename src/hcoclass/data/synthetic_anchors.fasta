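>HCO_anchor synthetic HCO anchor sequence (A1-type fingerprint, reference numbering)
KPTLVDTYFGGDDAYTRTDLTWWGRWILMMLNMYYTRPIQLYVEVTKLQADWYLLWTLGM
GYKFYWQERIVSRMMMPIDLSDYCTMWVLRASLHFNRGKVMIRPDCGKPIFDNTKKGYMP
LPLDNQYDNLNFASTCKQYFPQIGSVCQEDVVMNAWYYGANEVWINIKKVYAPNCNDKFE
RIMVMASNMILSSARKTANDKYDPRCCMKVVECPGQVIECFDQWKKNWGAQTSQQNVQAC
WAVNMYRMWPFFFEWWIEDIKYSTYIGGQERAEYEHYEWYSSNPTNIVKKSWCCRNEVVV
YITGVQLRECWAGIPPREENLFGWHHPDSPWMEPRQWGDRSLDELTLERCTKAKRTWMTD
KKRPSCVFTAGASKLAYFVFVEYNGAGLSEDVCIPGPGRRPIPNEWFESNHAHTLYSVAA
KICIPRGYLTDWPSTTGDTESVMEPNKQPPTNLQPDITRTWICDWALVSDYFMNFLENRE
YKEIVKYLPWYKVRLGPWLLSKGVPFTCEDVLGCRGKPVA
>NOR_anchor synthetic NOR anchor sequence
WPQWQSTFWICVWYMTVLDLTAICRFVLMMMNMYTTRPTNLFVELPDALNQMFITWTPLM
SFKFYEREYQVYVKAAPPQCMARVEFYVRQASLHFNRGPVPESPDWQKIIFDKTKKWWKF
LPLQNQYDNLIFAKTCKCIWATACMVTQPSLVMYYWNCKHSYFEFIPFDVFFGDCIKFFN
RARYNDTPMILSCARKTAWDKYDQRNFPFGDICGPGVIAMKRSWYEWRGANVSFQDVKSI
YAMEMTYFCRFFEEFSDEKGVYVMYEDDSYYDEYEHYMWWSSNKMLWVKKRWCCKLENNY
SESDQASRDPWFGIRKRWNFTFGWHHPDSLWREPWPDANMEWAWAQYERCQKASRTWTIM
RWNTVFVVTEVIGALIFFPFKEIPYADPDLKQDCLGNWVVQTAQLPFESNHAHTLYEVNA
PITSVMCMNGFDQVEDVIGRDVMEPNKQEMTNCSAQWMRTQICMPVIKDHHQFWRFLNWW
LKRGMDNCPGPEVDEQPPCKIKVNKFRAEGPPLCWVIPVK
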