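>LCL_1
GVYNQRQGISFSGMGIDICKCLKYKCIAKLTSWVCCWRENSKWKWGGPNNVYWHGSIFYP
VSNPKFSMYHQRLEVPNQNQNYEEKQTNILGKTSAHHWGGYARHMVHGTHMREMDEHCDW
AMIKMYCNPMIQPELRKAHASSHGWTFCCGMPVPPNEWRFSSPCLRPETYNLHVNKFPIP
WNCTWMALVEGDYYESAAHMRPFQATKQTCLKHIDIHKSSCPDLQNHSPEASATGLAPMY
KYCTAYVKHVTPDLSSIYKHVSDHHYIRKWWIRLDIVAFFFVEQNDFACGYIFKPPFWDH
>LCL_2
GVWNQRQGISWSGFGIDDCKCLKYKCIAKLTSWVCCGRENSKWKWGGPNNVYWHESIFYP
VSNHKFSMYDQRLEVPNQNQNYEMNHTNFLGKTAAHHYGGYARHMVHGTHMRDQDEHCDW
AMIKEYCNPMIHPELRKAMSSFHGWTKCCGMPVCPNEDRFSSPCLRPETYNLHVNKWPIP
WQATWMALKEGDYYESAAHMRSFQATKQTCLKHIDIHKSSNMDLNNHSPEASATGLAPMY
KSCTAYVKRVTPDLSSINKHVSDHHQIRIWWIRLDIVALFFVEQNDMACGYIFEPAKWDH
>LCL_3
GVWNQRQGIAFSHMGIDDCKYLEYKCIAKLTSRVCCWRENSKWKAGGPCSVYWHGSIFYP
VSNPKFSMYHQRLEVPNQNHNYEMKHTNYLGSNAAHHHGGYARHMVHGTHMREQDEHCDW
AMLKYQCNPMIHPELRKAMSSFHGWTFCCGQPVCTNEDRFSSPCLRAETYNLHVNKWPIP
WQATWMALKEGDYYRSAAHMRSFQATKQTCLKHIDIHKSSCMDLQNHSPEAEATGLAPMY
KMCTAYIKDVTPDLSSIYKHVSDHHYIKKWWIRLDIVAFFFVEQLDFACGWIVKPPKMDH
>DCL_1
DPGKQTKGHSFTDMKMDDNFCCAYKHLAELTSYITCWHKEPKSSWGRKNNHFWHGFIFWP
RSNQSYHMYHQPCEVPCCNQAFEEKFTFKFKKHAYGYHVSMKASALHGTDTPDIDCQMVW
AYFRFRKDIIIHCKREWVFRCLWAWTGCCGMPVCWKFECESTPHIRREQYEMSKDWWHIP
NAASIRELRRHDYSESGFKMVSFYGCAQTCCDHGAAGYHSILTDQNYSADASSTHLVPMF
KLATANVRPCQPWLSPIYWWVSNHNDIRKFMFSMRINGYELYGNPGWACGGISAPWKWMC
>DCL_2
GPGKQTKGHRFQDMKMDENFWQYYKHLAELTSYLTCWHKEPKSNWGRKNNHFFHGFIFYP
RSNQSYHMYHQPCEVPCCNQAFEEKHTFKFGKHAYGHHRSMKASALHGTDGPTIDCQMVW
AYFSYRKDIVIHCKFRDVFRCLYAWTGCCDMPVCWNFDCESTPHIRREQYEMSKDWWHIN
SAASIRALKRHDYSESDFCMVSFYGTAQTCCDKGCIGKHSIYTDQNYSADASSTHLVPQM
KLATANVRPIQPWLSPIYWWVANHNDIRVFMFSMRIHGGELYGNPGWACAGISAPWKWMC
>DCL_3
GPGKQTKGHSFQDAKMDDNMCQAYKHLAELTKYLTGWHKEPKSSWGRKNNHFWHGFIFYP
RSNQSYHGYHQPCRVPCCIQAFEEKHTFKFGKHAYGHHVSMKCSALHGTDGPHIDCQMVW
AYFRYRKDIVCHCKRRWVFRELWAWTGCCGMPVSWNFDCEATPFIRREQYEMSKDWWHIP
AAASIRELKRHDYSNSDWCMVSFYGTAQTCCDHGCIGKHSILTDQNYSADASSTHLVPMF
KLATANVRPIQPFLSPIYYWVSNHNDIRKFMFWMMIASYELYGNPVWACGGISAPWKWMI
>Starter_1
GIGMNTPGLNIYNNNKWDCKCSAYRTIPKLTEELTCWVEESNSNSGSKNAVYQHGDIHTA
QNNSKMSMYHQCYNIPLLNTHWEKQHTMYCTKTAHNHEVSIKRHQLHGTNMREHYCWCKM
AMVKYWVGPVMHCKRRYAYTCMEGWTHCCCMPVFGGFHRESQPCLAREVYMASKDEWHIP
WAATLMAVPERQWLEEWQAKSSFWATAAMCGPHGCIQKYQINDLQNLSRDLSYTYLSLFY
HMALWYIRDVCEDLSPIYHMNSNPHTARQFYISGRIFYFEMKEQIRWACGQISAPWKCDI
>Starter_2
GIGKNTPGLNFHNMNKWDGKCSAYRTIPKLTEELHCWVEESNSNSGSKNAVYMHGDIHTP
DNNSKRSTYHQCYRIPLLQTHWEKKHTMYQTHTAHGEELSIKRHKLHGTNMREHECPCKW
AMVKDTVGPVIHCKRRYATTCMEGWTHCCIMPVFGGFHRRSTPCLAREVKMASKDEWHIP
WAASLMAVPESQWLEEWQAKSSFWATAAMYGPHGCIQKYQINDLQNLSRDLSYTYLSLFY
HICLWYIRDVCKDLSPIYYMNSNHHTARQFNISGRICYFEMKEQIEDACGQISAPWKCGI
>Starter_3
GIGKNTPGLNVHNMNKWDCKCLAYRTIPKQTEEVTCWVEESNSNSGSKNAVYMHGDIHTP
QNNSKFSMKHQCYRIPLCYTHWEKKHTMYCTKTAHGHEVSIKRHKLHGTNMREHECWCKW
AMVKYWVEPVIHAKRRYATTCMEGKTNCCVMPVYGGFHRHSTPMLAREVYMCSKDEWHIP
WAASLMAVPEPQWLEECQAKSSFIRTAAMLGPHGCIQKYQINDLYNLSRDLSYTYLSLFN
HMCLWYIRDVCKDLTPIYYMNSAHHTKRQFYISGRIFYFEMKEQYRWACGQISAPWKCDI
>Cyclization_1
GPGKGTDGLSFSNMAMDYCECQQYNCIYKCTNQLTVQSKPGKSKLGGKNIAIWHGDFFYQ
QSNTTFSMYHIPNNVPMINQAYEKKHRWYPGKTAHGHHVSVYRNVLHGTHMRDYSCHAHW
AMVKFPVNQVVPCRHGYVLSCRSGWTHCVASPVVNNGDRHNTFYAQHENFGFRKDFWHAQ
FHYSLMVSKNPDYVPSDPFMMTFHATSQVCLAHGQVLKHSISTLKNLDPNAESTYLSPNV
GMCNIYVKPMTPDLSGIYMLYSNNHSWRKFWISLRVHNFQMLEQIHWASAQLDARWKYEC
>Cyclization_2
GPGKGTDGLSFSNMAMDNCECQQYNCIAKTTNQLSCQSKCSKSKWGVKNIAICHGDYFYQ
QSNTTFSMYHIPLNVPMINQAYEKKHRWYPGKTAHSHHVSCKRNVLHGTHMRDYGCNAHW
AMVKMWVNQSVPCRRGYCMSCREAWRHCVASPVWNNGDRHNNTYPQHEPFGFRKDFWHAQ
FHANLMVSKNPDYVPSDAFMMTFHATSQVCLTHGQVLKHSISTLKNLDPNAACTYCSPNV
GMCNAYVKPVTPDLSGIYMLYSNNHSWRKFWISLRVHNFQMLEMIHYACAQLQRHWKYEC
>Cyclization_3
GPGKGTDTLSFSNMAMDNCECQQYQCIAKTTNSLTCQSKESKSHWGGRNIAIWHGDFFYQ
QSNTTFSMYHIPLNVPFINKAYEKKHRWYGGKTAHGHHRSVKRNVLHGTHMRDYGCHAHW
AMVKFWVNQVVPCRRGYCMSCRSGWTHCVASMVSNNGDRHNYWYAQHENFGFRKDFWHAQ
FHASLMISKNPDYVPSDAFMMTFHATVLVILAHGQVLKHSISTLKNLDPNACCTYLSPNV
GMCNAYVKPVTPDLKGIYKLYSNNHSWRKFWISLRVHNGQMLEQIHFAIAQLQAHWRYEC
>Epimerization_1
GPGKKTFMHSFQNMNMDRCKCQVYKIVLQLRSRLTCWVQESKMEWNYKNNVYWHGGIFWP
QSDEMYPVYHQPLEVPHANQAYLKSHTFWPGRAGHKHHMSWKIHMLAGVRMKDTHCHMVY
AMMQYMTNPSIHRKKRYAMSALHGYTSLSGNPVMNNYDRDHTPELRRESFYLIRDEWHIP
WAPMLMCMKEVDYINSDRAMRDFYVTGHMCLGDGCIAKKSILDAQHRSDDASNTALLHMW
RICNAHVKPIDPKVSPLVWFVCNFFTIRLFWRSLRIHHFEIFERDHSISGMISDPWRPMD
>Epimerization_2
EPGKQTRGFSFQNMNNDRCKCQVYKVVLQLRSMLTCWVQESKMEWNYKNSVYWHGGIFWP
QSNEMYPMYHQFLEVPGANQAYLKGHTFWPGRARHKHHMSWKIHMLDGVHMKDTDCHMVY
AMIQYWTNPSIHRKKRRAMSALYGWTHLSGNPVMNNFDRDHGPELRKESFYLSRDEWHIP
WFPMLMCMKEADYINSDRAMRGFYVTAATCLGDGCIAKKSILDAQHRSDDASNTWLLPMW
RICQAHVKPIKPGVSPLVWFVSNFFTNRKFWISLRTHHFEILERDHPISGMISDPWKPMD
>Epimerization_3
GPGKQTFGHSFFNMNWDRCKCQVYKVVLQLRSRLTCQVKESKMEWNYKINVYWHGGIFWR
MSDEMYPVYHQPLEVPHANQAYLKGHYFWPGRIGYKHHMSWKIHMLDGVEMKDTDCHFVY
AMIQYWPNHSIHRKKRYAMSALHGWTHLEGNPVMNNFDRDTTDELRREVFYLSRDEWHIP
WRPMLMCMKEPDYINSDRAMRDFYVTAHTCLGDVCIAKKSILDAQHRSDDASNTWLLPMW
RLCNAHVKPIDPGVSPLVWFVSNFFTIRKFWISLRIHYFEVLERDHSISNMISDPWKPMD
>DualEC_1
GPESQTNGLSFHEAKVDRLKCLDYKCCYKPPPWLTYWVKESKSAWSGNNNVYWWDIWFYA
QFRPTFSQYWQPLEVSCNNQHHELKHWFYPGYTGKGRHPGIKSRPLHNTLMRDQNSHCVW
AMETYWVKEVIHYKRRYATKILEGVTHCAGMPRANNFERKSTMCIDREQYNMCKPEWHIP
WAASLLALKEPSYVESDPPSHSFICTYQRCLPHGCVMKHSIVDWQDCSDDIYGTHLVPMY
KMVTHQVGVVRTDLRIYYFFVMNHHIFVRLSIPVRMHSFEPLNQIHWPLNQISDIHKYAC
>DualEC_2
GPRQQTNGLSFQEAKVDYLKCLTYKMIYKPPPWLTYWVKESKSAWSGNNNVYWHDKWFYA
QFRPTFSQYWQNLEVPCNNQHHPLKHWFYVGYTGKGPHPPIKGRPFHNTLMRDQNSHCVW
AMEKYWVKEVIHCKRRYATKILEGVTHCCGMPQANNFERKSTMCIRREQFFMSKPEWRIP
WAASLMALKEPSYVESDHPSHSFICTYQTCLPHGCVMKHSIVDWMVCSDDIYSTHLVPMY
KMVTHQVGPMRTDLRIVYFAVMNIHTFVRLKIPLRMHSFAQLKQIHWPCNQISDAHKYAC
>DualEC_3
GPEDQTNGLSFQESEVEYLKCLKYKCIYKPPPKLTYWVKESKSAWSGNVNVYWHDMWFYA
QFKPTFSQYWQPLEVPCSNVHHELKHWFYPGYTGKGRHPGIISRPFHNTLMRDQNSHCVW
AMEKYWVREVIHCKRRYATKILEMVDHCCGMDRANNWERKSTMCIRREQYNMSKPEWHIP
WAASLMACKEPSYVESDRPSHSFICTYQTCLPHGCVIKHSIVDWQDCSEDIYKTNLVPMY
KMVTHQVGPVRTDLRIVYFFVMNHHTFVRLSTPLRMHSFEQLKQIHWPCNQISDGHKYAA
>ModifiedAA_1
GPGKQTSGLSWQNGKMDDNKCEAWKMVAKYTQALKMLVQESKSRLNDKHNVAVHGDILYL
QMNQKFSMYHYWVEDPCMNDAYEKRHTFYPAKTAHCNHTSVKRHMLYGLIWRDLDCPGVY
AMWVYWINGVVWCARRYAMQWLNGWQHNCQVPVTNNYDLTSTACWRFRNHNLDKDFWHWP
YAYSQMKLWMPDLVESDAVMRSTAGSAHTVRPHDVIMKHPDLDLQNFSSQASCTYLRPMY
YMCTAFIAPVSNTTGLIVYFTDNHHTFHEFWINLRICSFEMLEPFHWMCGQKSTPVSWAC
>ModifiedAA_2
GPLKQTSGLSWQNGKMDDNKCEAWKCVAKYTQHLKPLVQESKSRQNDNHNFYVHGDILYL
QMRQQFSMYHYYVEDECMNDAYEKRNTFYPAKTAHCMHTSVKRHMLYGLIMRDLDCPCVY
AMIVYWINGVVWCARRYAMQWLNGWTHPCCTPATNNYDLTSTPCWWFRNYNLDKDEWHFP
YAYSQMKLKEPDLVESDAVMRSCAGSIQTVRPHDVIMKHKDIDLQNFSNQASWKYLRPMY
YMCTAFIGPVTPTTGLIVYFSDNHITMHEFWINLRITSFEMLEPIHWLCGQKSTPVSWAC
>ModifiedAA_3
GSGKQTSGLSWQNGKMDDNKCEAWKCVAKYTMHLKSLAQESKNRLNDHHNMYVHGDILYL
QMNQKFSMYHYYVEDPCMNDAYEKRHTFYPAINAHCNHTSVKRHMLYGLIRRDLDCPCVW
AMIVYWINGTVWCARRYAYQWCNGWTHNCQVPVTNNYDLTSTPCWRFRNYNLDKDEWCFP
YAYSQMKLMEPDLVESDAVMRSCAGSAQTVRPHDVIMRTPDLDLQNFSNQASCTHARSMY
YMCTAFIGPATPTTGLIVYFSDNHHTFHEFWIPLRICSFEMLEAIHWLCGQKSTPVSWAC
>HybridC_1
APTKATSGISFEQMFFGSCKSHAHKCIARMPSYVTRHTRESKSKYGGKNGVMCHGSMFRP
QSNPTFSVYYFPTENPCMNQAVEKKPTFYTGKDANGHHVNLTRHVVHSTFMRQQDKQIVW
GMIKYWINSVSQCKRLYKMSCLNGSTQCCAKNVCNNFDSHATLMLERKWFNWKYQTWHIS
WCAQLMALKEPDHTVSDAMMRDFYATAQTCLDSGCILKHSFLDWQRLSDDPSLRYLVPHV
KTCLDYVGPVKGDLDIVYWRVSKHSTIQKMWISVRIHSEEMYEQWHHAATTISARTKWHC
>HybridC_2
APTKATSGISFEQMKFGSCKSHAHKCIARMPSYVTRHTRESDSKYGGKNSVCWHGSMFRP
QSNPTFSQYYWPTENPCMNQTMEKKPTFYTGKQAHGHHVNLTRHVVHNTHMRQQDKHIVW
GMIKYWIMSVSHCKRRYKMSCFNGSTFCCATNVCNNFDSHCTLCLRREWFRLKYQTWHIS
WCAEAMALKEPDHTVSDSMMRDFYATAQTCLDAGCILKESMLDWQNFSDDPSLRYLVPHH
KTCLDYVKPVKGDIDILYWRVSKHSTTQKVWISVRIHSDEMFEQWHRAATTIGAPWKWHC
>HybridC_3
APTDATSGASFEQMFFQSSKSHAHKCIARMPSFVKRWTRESKSKYGGKNGVMWHGSMFRP
QSNPTFSVYYFPTENPCMNQAVEKKPTFYTGKDAHGHHVNVTRHVVHNTHMRQQDKHIVW
GMILYGINSVSHCKRLYKMSCLNRSTFCTATNVCQNFDSHCTLCLRRQWFNLQYQTWHIS
WCAQLMALKEPDHTVSDAMMRCFYATAQTCLDAGCILKHSMLDWQNLSDDPSLRYLVPHY
QTCLDYVKPVKGDLVTIYWRVSKWSTIQKVWISVRIHSDEMFKQWHHAATDLSAPWEWHC
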