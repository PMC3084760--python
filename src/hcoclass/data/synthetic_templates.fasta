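>TEMPLATE_A1 synthetic A1 type template
KPTLVDTYFGGDDAYTRTDLTWWGRWILMMLNMYYTRPIQLYVEVTKLQADWYLLWTLGM
GYKFYWQERIVSRMMMPIDLSDYCTMWVLRASLHFNRGKVMIRPDCGKPIFDNTKKGYMP
LPLDNQYDNLNFASTCKQYFPQIGSVCQEDVVMNAWYYGANEVWINIKKVYAPNCNDKFE
RIMVMASNMILSSARKTANDKYDPRCCMKVVECPGQVIECFDQWKKNWGAQTSQQNVQAC
WAVNMYRMWPFFFEWWIEDIKYSTYIGGQERAEYEHYEWYSSNPTNIVKKSWCCRNEVVV
YITGVQLRECWAGIPPREENLFGWHHPDSPWMEPRQWGDRSLDELTLERCTKAKRTWMTD
KKRPSCVFTAGASKLAYFVFVEYNGAGLSEDVCIPGPGRRPIPNEWFESNHAHTLYSVAA
KICIPRGYLTDWPSTTGDTESVMEPNKQPPTNLQPDITRTWICDWALVSDYFMNFLENRE
YKEIVKYLPWYKVRLGPWLLSKGVPFTCEDVLGCRGKPVA
>TEMPLATE_A2 synthetic A2 type template
DVTGNPFFCGQVWMMVDLDLTMIGPSYTMMPNMYYTRPQYLYVEARVADKCMYLKWFCLG
GMPFAAGGYWCECKMAMTQVNSYVEMWERIASLHFNRLPVRIQGSKQKSIFDNTKKNYKR
LPLDNQYDNLNFASTCKYNDLKSGMVMSVDIVMPDWNNTFYEMWFNDNYVYPPNCKYKNR
RSIVNLSYMILSSARKTANDKYNIRLCMPAQMCEGAYIWMNMQWYAKVFANSSKQKREWP
FTKSMTDMCFFNEEGIDEKICYWNYGVGCYNLEYEHYYWYSSNPTLWVKKSWCCFLEMIY
GFPTFTRLFPWLDIAKQDDIWFGWHHPDSEWMRGLQKGDYSRRPKVTERCTKAKRTWRQF
QPRTSVVWTWGAEDLASCNLQVYNFAVPYGDACALGFYVAFGLENPYESNHAHTLYWVAA
WIEVDWDQDILGSVVTVDTSAVMEPNKQGPCKAEQQEIGTIISLMYLVDIGAMQWWENED
RPEFVRIQPKCKVILQATMVTILRSMAFIKVLDKINSPMI
>TEMPLATE_B synthetic B type template
WCQWNSTFIGESGAMPDVSLTGMWRAYLSMSNMYTTRPIYVFVGVFDALSDMYDTWYYNT
YCEFEAWRYGVDRKDAPVQWRGYVEEWVRQASLHFNRMDVEIYQDLGMPIFDKTKKNQKP
LPLQNQYDNLIFAKTCKYYFEKPFITVTFDVVMWPFYVGDNESTFIDMGVPEPNCFQKLN
ADYVNLSNCILSCARKTAWDKYDDRTQNQQQDIPLQNTEMFSSWCPYQGVNSWWQDFKGI
NATEMTYMCDFSKRRADETMMYVNEIDKCYFEEYEHYMWYSSNPTCWVKKYWCCFLEMNK
TKSLRFNRDPAANIPKIQETRFGWHHPDSPWMGPMQKGDYSVFPVTCERCSKATRTWRTD
CWSTSSVMTWGAKALCFDYRYWGQMAMCDWLQCADGMQRNQQAQFPEESNHAHTLYTVAG
NNTIDVGPDTPGQVGTCDQFSVMEPNKQGPTFLQAQAPRTNECVGRLRSYIAYQQPEGQM
WMEPRLNTLCATCVEQQTMWVMWCGFYQEIALPCISCPQG
>TEMPLATE_C synthetic C type template
WMMWNSTFVIGYWTITATDATFWWRNYEQPPNMYTTRPDYMACCWQIAMDGMELLWYNLM
NKIFFGCEYVDFYKLSPTQKVGYVEMDVWQASLHFNRYPVRIQPDFYKVIFDKTKKNYLP
LPLQNQYDNLIFAKTCKIYDCPDYGVCPQKVKMGFSYTGDRVSWGRMEKVYQVNFKLWFT
RAYKNLCNDILSCARKTAWDKYDANLCKLPPVDSFQIIWMTSVWYKIWPAEQSTQMQKWR
YAVPMTYMCRAEENWPSSSGWYCQYIRMCCKLEYEHYMWWSSNPTFWVKKYWCCFLEMPN
AFSSMQTRDWWAYACMGEWALFGWHHPDSISGEPGQAGDYRLMSKSIERCSKASRTWNTI
ISPTSDVKTLGAYISATFTFYTINKLCPLVDQCFECNWNNWTLQFGFESNHAHTLYDVAA
YSTSDEMPIFIGEPEGCFTRRVMEYNKQGPTCLQFTVTRTTIRYGAPVDECAMFFFQGQP
CREFELQQACPKDCEQEWVKANENQFRPEKVVCCPWSTCG
>TEMPLATE_NOR synthetic NOR type template
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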