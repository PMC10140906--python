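>PBcons_A clade=A role=consensus
MMRGGGMYCSNIPGHRSPYPFQIFDLTVRVVSNFKKERMNFDFNEQYISLWNIPLGKDFL
RQLKPQYKHHMSMDWHMTNFKCHANFKWRMKERDTIEVKAMTNGGLKRYFNLTKQNTSAK
GFRTYLTKLNPNGQDQHQSCYFQIIIHLEAMVLHRQKPPHQQNLVSNQHATSPYNQRLML
NNGQEMRPCFALEGVDDGIARKPRNCTWIRYYYNSWWMMLDKQWATAAQRMCMKEHWDLC
LPYQIIDMTTDPGDSRWMRYLGHAEPQMIHRPDKPWFLMPFLTDFEVAPLNRKSYGIKQN
IMIHMYNHFWFGWCTGPDKIHAWLHDKYWMTIVRCSHAFRDSMCMICEWKLDAITHWSEN
REPSYWKANSFCTLMVMYHMLFIQPLNCRDINYFKQNRGAHADEGENDNNSSWKWSVMPH
RVGWPLVRSLNVYVYQNIQYDQNKTLMRYFLHHYHTWYMEKPWFYICTGNYGSTCTFRQH
QYVDKWRWCGCNLANACHELTEIFSVCCRPDYINHPTSLLKGCKIEKCISQSHCGADPNS
DCHNAWCAVNNWLACEDPHCHWLVMESWMAIDRYLYYKTA
>PBref_A1 clade=A role=reference
MMRGGGMYCSNIPGHRSPYPFQIFDLTVRFVSNFKKERMNFDFNEQYISLWNIPLLKDPL
RQLKPQYKHHMHMEWHGTNFKCHANFKWRMKERCTIEVKAMTNGLLKRYFPLTAQNTSAK
GFRTYLTKLNFNNQDQHQSCYFQIIIVLEAMVLHRQKPPHPHNLVSNLHATSPYNGRLML
NNGQETRPCFALEGVDLGIARKPRNCTWIRYYYISTWMMLDKQCATAAQRMDMKERDDLC
LPYQIIDMTTDPKDSRWMRYLGHAEPQMIHRPDKPWFLQPFLMDFEVAPLNRKSNGIWWN
IMIHGTNHFWFDWCTGKDKIHAWLHVKCWMTIVRCSHAFRDSMCMICEHKLDAITHWAEN
IEPSYAKTNSFCTLMVMYHMLFIQPLNCRDINYFKQNRGAHADEPENDNNSSWWWSVMPI
RVFWYLVRSSNVYVYQGIQYDPNKTRMRYFLHHYHTWYMEKTWFYICTGNYGSTMHFRQQ
QYVDFWRWCGCNLHRACHELTEIFSVCCRPDYINHPPSRLKGCKIEKCISKSHCGSDPNS
DCHNDWCAVNNWLACEDLHCHWLVMESSMAIDRSLYYKTA
>PBref_A2 clade=A role=reference
MMRGGGMYCSNPPGHTSPYVFLIFDLTVRVVSNFKHERMNFDFNEQYISLINIPAGEEPL
RQLKPQYKHHMSMAWHMTNFKCHANFKWRGCERDTIEVKAMTNGGLKRYFNLTKENPSAK
GFRTYLTKLWPNMQDQHQDRYFAIIIHLEAMTLHRQKPPHQQDLVSNLHAKSPYNQRLML
NHGQEMRFCFAHEGVDDGIARKPRYCTWIRYYYNSWWMVLDKQWATAAQRMCMKEHWDLC
LPYQIQDMTTDPGDSRWMRWLGHLEPQMIHKPDKPWFLMPFLVDFEVAPLNRKIYGIKQN
IMIHMYNHFWFGWCTGPDPCHAWLHDKYWMTIVRCSKLFRDSMCMCCEWELDAITHWSEN
REPGYWNANSFCTLMVMYHMLFIQPLNCRDINYFKQNRGAHAREGENDPNSSWKWSVYPH
RKGWPLGRSDNVYVMQNIKYDQNKTYMRYFLHHYHTWYMEKPWFYLCTGNYRSTNTFRMH
SCVDWWTWCGGNLANACHEVTEIFSVCCDPDYINHPTSLLKGCKIEKCISQSHCGADPNS
DCHTAWCAVNYWKVCESSHCHWLVMESLMAIDRYLYYKTK
>PBcons_B clade=B role=consensus
MTRGPAMHVSGWPEFGSPCGFQIFDLSQKMESLQIREKMYFCADEQYFSFHTRPEGKDTL
TQSCPTMKHHMLMDSHATNFICMMNEMWCMMSRDTIENPAVWNPNDARYIVQTKQEHPVD
GFRTFLTMCAPLGQDVHQSWFVQVIIHLEAFVLHNQDGPGQWYDDSNKYAFSPYHARLML
NNEQEMRCPFAFEGMDRTIVAKWINCCWDRTLHNSPFMMLRKIWWTVRKMMCMKEHIKSC
QPYQFIDISTDEGLSRVTRDFGHAETMMIHNMLGWWFLIPCVFQWEPVPLNMKVYIQIQE
IMIHLMNNFMMPWRMQPDKNQCWVHNVYGGNIWGCSKLHFDMMYYKIEWKPKASTHWSEN
MEPSLWKDNLRCTLEFMYHMLFIQPLNCRDINYFKQNRGAHADERVNCCFRYSGKSIMYK
AVGDPQAHNLLPANWAYWDGDQNKTATWIQLHHMHMWYVIVLWFYLTTYGFWSTCTSRVH
QRVDKWRWSSARFNFACMEVYQIPSVFKVPDEMPHPTSGLPSCSPKKCREILHCPAWEAW
DCHVIWCAYNSYDACPDPDCNKLVVESFMADQEKSNYITM
>PBref_B1 clade=B role=reference
MTRGPAMHVSGWPEFGSPCGFQILDLSQKMESLQIREKMYFCADEWVFSFHTRPEGKDTL
TESCPTMKHHLLMDSMATNFIWMMNEMWCLMSRDTIENPAVENPKWARYIVQTKQEHPVD
GFRTFLTMCAPLGQDVHQSWFVQVIIHLEAFVLHNQDGPGRWYDDSNPYAFSPYGLRLML
NNEQEMRCPFAFEGMDRTIVAKWINLCIDRTLHNSPFMMLRKIWKTVRKMMCMKEHIKSC
QPYQFIDISTDEGLSRVTRDFGHAETMMIHFMLGWWELIPWVFQWEPVPLNMKVYIQIQE
IMIHLTNNFMNPWRMQPDKNQCWVHNVYCGNIWGCSKLHWDMMYYKIEWYPKASTHWSEV
MEPSLWKDNLRCTLCFMYHMLFIQPLNCRDINYFKQNRGAHADERVNCCFRYSGKSIMYK
AVGDMQAHNLLPANWAYWDGDQNKTATWIQLHHMHMWYVIVLWFYLTTYGQWTTCTSRVS
QRVDKSRWSSARFNFACMEVYQKPSVFKVPDEMLHPTSYLPSCSPKKCREILHCPAWENW
SCHFIYCAYNRYDRCIDMDCNKLVVEVFMAIQEKESYITM
>PBref_B2 clade=B role=reference
MTRGPFMHVSGWPEFGSGCGFQIFDLSQKMESLQIRMKMYGCTDEQYFSFHTRPEGFDTL
TQSCPTMRHHMLMDSHAFAFICMMNEMWCMMSRDTIENPCVENPNDARYIVQTKQEHYVD
GFRDQLTMCAALGQDVHQSWFVQVIIHLEAFVLHNQDHPGQWYDDSHKYAFSPYHARLML
LNEFEMVCPFAFEGMDRTIVAKFHNCCWDRTLHCMLFMTLRKIWWTVRKMMCMNEHIKSC
ADYQFIDISTDNGLSRVTRDFGHAETMMIHNMLGWWFLIPCVFQWEPVPLHMKVYIQIGE
IMLHLMNNFMMPDRMQVVKNQCWVHNVYGGNIWGCQKLHFDMMYYKIEWKPKASTHWSEN
MEPSLWDDNLRCTLCNMYHMLFIQPLNCRDINYFKQNRGAHADEKVACCFRQSAKSSMYK
AQGWPQRHNLLPANIAYWDGDQNKTATWIQLHHMHMWYFIVLWFYLTTIGFWSWFTSRVH
QRVDKWRWSSVRFNFACMEVYQIPSVFKVPDEMPMPISGLPICSPKKCREILHCPAWEAW
DCHVYWCAYNSYFECGDPDCGKLVVESFMADQEKSNYITM
>PBcons_C clade=C role=consensus
MNRKPASYCSNFIEHHSFMCFQIFDVTDKVVSNHSRELMYFDFNEQYTSLWHYPIIKDFF
RQCKPMYKIHQMYDSHWTNFRCMALEMKLGWVRARIQNNAWPNNSPKRYFVSTKQNHSAS
GFTTVLTCTNPQGQDVMQSLYFQVIIYLICFWLDEQMPPPQEYLDSHTPCFSPFNQVLIL
NEGQEMRVCFRFEGMDDVIVRKPNNSCLWRMYYDSPMYMLDKIEATGAYCMCMFEHIKNC
CPYQFIDHSTDLQLDRMISDLGHAETQHIHRQDPWWSLNPFQWMFENVCLLEKLYGICQE
IMRQSYNGFWFHWGLQPGCDGCCVHSVCGGKIQGCSSLFKDLMDYNIEWNQTAWTSSPCK
GERSLWGDNSFTTDETFMHMLFIQPLNCRDINYFKQNRGAEQMEGVNADDVKSKFSVMYH
AFGDPQVRMSNPNVWANFLYDQKMTPMWIFAIHWHMWYTIKLWAYICCKGYWSGSTSRHP
MAWDLSRWNPHIFNHACMEVCQIPEDCCEPDRPNHQTAWLARCKTHKCREDSHCSAQENS
DCHNEHCEINSYLVCEDLQCDWLEPESWMLSDEPLKWKTA
>PBref_C1 clade=C role=reference
MNRKPASYCSTFIEHHSFMCFQIFDVTDKVVSAHSRELMYFDFNEQYTELWHYPCIKDFF
RQCKPMYKIHGMCDPHWTNFRCMKLEMKLGWVRARIYNNAWPNNSEKRYFVSHKQNHSAS
GFTTALTCTNPQGQDVMQSLYFQVIIYLTEFWLDEQMPPPQEYLDSHTPCFSPFNQVDQL
NEGQEMRVCFRSEGMDDVIVRKPNNSCLWHMYYDAPMYMLDKIEATGSYCMCMFEHIKNC
CPYQFIDHSTDLQLDQMKSDLGHAETQHIHRQDYWWSLNPFQWMFENVCLREKLYGICQE
IMRQSYNGFWFHWGLQPLCDGCCHHSVCGGKIQGNSSLFKDLMDYNIEWNQTAWTSSPCK
GERSLWGDNSFTTFETFMHMLFIQPLNCRDINYFKQNRGAEQMEGQNADAVEQKFSVMYH
AFGAPQVRQSNPNVWANTLYDQKYTPMWIFMIHWHMNYWINLWAYICCKGMWSGSTSNHP
MAWDLSRWNPHIFNHACMEVCVIPEDCCEPDRPNHQWAWLPQCKTHICREDLHCSAQSNS
DCHNEHCEINSYLPCEDLQCMWLEPESWMLSDEPLKWWTA
>PBref_C2 clade=C role=reference
MNRWPALYCSNFIEHASYMHFQIFDVTDSVVSNMSRYLMYFDFNEQYTSLWHYPIIKDFF
RQCHPEYKIHQMYDSHWTNFRCMALEMKLGWVRARIQNNAWPNNSPKWYYVSTAQIWSMA
GFTTVLTLTNPQQQDVMQSLYFQVIIYLICAYLDEQMPPPQEYRDSHTPCFSPFDQVLIL
NEGQEMRVCFNFEGMDDVIVRKPNNSCLWRMYYDSPMYMLDYIEATGAYCMCMFEHIKNC
CRYQFIDHSTDLQLDRMISDLGHAETQHIHRQDPWWSLNPFQWMFLNVCLLEKLYGICQE
IMRQSYNGFWFHWGLQPGCDCCCVHSVCGGHIQGCSSLFKDLMDYNMEWNQTAWTESWQK
GERSLWGDNSFTTDETFMHMLFIQPLNCRDINYFKQNRGAEQSEGVNADDVKSKFSVMYK
AFGDPQVRMSNPNWWANFLYDQKMTPMWIFAIHWHMWITIKLWAYICCKGMWTGSTSNHP
MAWDWSRWNMHIFNHACMWHCQIPEDCCEPDRPNHRTAWLARCKTHKCREDSHCSAQENS
DCHNEHCEINSSLVCEMLQCDWLEPESWMLSDEPLKWKTA
>ISout_1 clade=outgroup role=outgroup
MMYLAMYLCVPLVAQPVGQSWSVQKCFINFNPLDENSGEPAFEIWVNTLDDINMNRMKNE
WWQRFTMMSHSEMSFFENDAMTRQGHMWSFTWHFFTAGSGSGWDMYWIWGAVKPPPAGEH
YIDIMTNCRSWDKCYEQQTDGPEIATSGIIGPCWWAAEWEMMAKYEKWTTMRGKKPQERE
ISQAMCGLWPWWGLLETYPSYVNCEWETYMIQGMKDCKHLRPYETIRKIVDEDDIICDNR
TWSAHFVNMHKDEIDLDGYCNAHESMHDAFTCRWIRVLLCISIWMPPHSWTPRMHVNFNM
RICSHWRALRHCSGRYRLDGRFYTHWCFGPSVFVEWYRHMTQPNLPNLRCSKGLHMDNFK
LAHEWMWIFDPTGIGLHVPEFAQNQGYGPPWIEPPDTTTHFWSPIVIKEERYEIDTTTTP
>ISout_2 clade=outgroup role=outgroup
MVKYIASGQDPSCEDTISPNFASSMYKFFCILKQGDWCSFAMNECLWQARGWTPYEGHYL
LGMLNLTMIDVDDFMCDVAYKYLFMETDQLFGDDDTHETMVMFPVMLHAATLGCAPDDGF
TALVLYYKINTKSLLWPIYFHRYLDSDADRYVELEWGPHMSVTGRCIGRLTSHRDAPTYT
YWQLSCYAWAFHAGFSYHGHDGLMCNHWECRCSPYWCILFQWCIGMTGPMNAFKHPAHCF
PGPFSSHAARCTPAGFANFPPWWTSQDFRNDKVDHYDHREFDNQYNDKFDWMMFCGRDAQ
GCRPKCESGIYQFVFACGHGWRPLKQGDLVCQFQFVALQQINIQHRRLDKVWVENYAQSN
PGYKYIFEPRGCFSCVDGNFTYKAYKYCNQPEQSIKNEGYYRMFYPMMWVKGLSQWWHWC
>ISout_3 clade=outgroup role=outgroup
MRNDWHNVYPNTKRSFGNFNPAKPWNSSKQEGWNSTLLIESPKNDKCWSMNCPAQMKRIH
GQEFDRPFKSRKHDVHCCILIMNSKDYNYKSSVNDALHCSSRAEHTYCHRQSGCILDPWV
MYHWTCPCFRSDQPCKYKGADFVWWKEHLLNQNMLEIVAWFRGAMYPAMMRKVWYRVEPW
NGPWESDKASVPLKHGGLSFQQWVLHPWCEQIKPLTTKPTHFKSSWDYCEYFMFHEQKDM
IAFCSCVHMMMAVHVTKHEISATYEGVFTGFMNENIAVVIDYKPSSLYYDAEMLFMWMHS
ITHPDQTHRNLKHTCKYVMGYLVMTWGPCVEIRQMDLATYDDNELGKDSTNPCSGVCWQG
QGMYFHYCFQNKHWMMDREIWMGQQWVYNWVRQRERAVSQSVKRVFHSVTHKWVTIYYFI
>ISout_4 clade=outgroup role=outgroup
MCYMLRIWVFSPFVVPQMKGKYEWGHFWFTYGHAIVVSPHNILDQLWKNCGRFPECSFDT
LPNWPHICGMLNNRAGSSEAWSPTFNVYSAEFHHRTSTIPQWSYVVYKEMNTGGVPLFVP
VINNMWYVDDQHPLVRNGCKELLKMTGTVQKKCTIIIYWIRMGPAQRFCRITVNMIDSRS
EELDWWQPIHMTFTLDGLRILTRHCHYRFISDLFLFMSWAILHMQSHRYCHEYECSDSIV
SLVFLKKHLGWWLMQCATEKTMGLETRVGATVAEVDREAYLQWTCHRVVMPEHSEHILKQ
SPKTIEGQLRHIMAGYCGCGQRTCLQGCVSYYGRVASRGAEHGGMIHLACNTQTKTNASG
YSTLGKMYRHCAQDEQVVSSDARVIDLDTAGYRSQMQRSMTLCYEACQSEKSIYMVNCLN
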