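>Rn_rhodopsin
MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLY
VTVQHKKLRTPLNYILLNLAVADLFMVFGGFTTTLYTSLHGYFVFGPTGCNLEGFFATLG
GEIALWSLVVLAIERYVVVCKPMSNFRFGENHAIMGVAFTWVMALACAAPPLVGWSRYIP
EGMQCSCGIDYYTPHEETNNESFVIYMFVVHFIIPLIVIFFCYGQLVFTVKEAAAQQQES
ATTQKAEKEVTRMVIIMVIAFLICWLPYAGVAFYIFTHQGSDFGPIFMTIPAFFAKTSAV
YNPVIYIMMNKQFRNCMVTTLCCGKNPLGDDEASTTVSKTETSQVAPA
>Sp_opsin_1
MGNPEGPNFYTPFANKTGVVQSPIELPQNYLAEPWQFSMGAASMFLKIMLLFPINPLTLY
VTVQEKKLRTPANYFHLNLAVADLFAVFGAFIMTWYTSLNGQFEFGPTACNLEGFFALLG
GCLALWSLRELAIERYVVLCKGMSNQRGEENHAFMGWAFTALTALTCDAQPLVGWDIIIP
EGMQCVCGIDYYTPHEEKFDEPFVIYMFWVHMINSNIVWFFCYTQLVETVMEAAAKAQES
ATTQKAEKEVRRNVIITDIATLICWLPPAGVAFYIFTHPDVDFGPIFMTIPAFFAKTSAV
YNPVIYIMMNKQFRNCMVTTLCCGKNIDGDTEASDTVSKCETCMLAPADMNVTRQMEPSI
C
>Sp_opsin_2
KAGTRHFVCQFPFCQVTGVVISWFPESQLYSALQWNFNMQAAYMGNYISLTFPIFNTTLI
RQVQQAINRTPLNYFLNVLATADLFMVSDGFTKTLYWWLHGVFVEGAFGCNLYMIFHTLK
GIYAYWSRVVLAMERYVGPAKPMSKFLFPKNYAGHGSKISCKLALPRAENVVVFWKHYIP
EFMTLNCGIDYYTPDERTNYHYVMEYTFTQHFQMCCIVIWYSYPTLVRGYAEAAKQQQEV
VHTANFEKITTCHIYISDFMFLICWEPHAQVAPYDFGHGGSDIWNPCMTIPPMFVKLICV
YNPVIYIMMNKQFHPCRVGTMCCGKFPKHYSEFSDHVNSTEWFQTCPV
>Sp_opsin_5
YAGTRGFVPQFCFCQVTGVVRSWQEESQLYLAEQWNFNDQAAYMGNYIMLEFPLFNDTLI
RQTQHAILRTPLNYFLNVLATADYLMVSDGFTNYLYTLLHGIFVEGATGCNLYMIFQKLG
GIIAYWSPVVKAMERYVGPAKPMSKFLWPEEYAVMGSAISAAQALPRALNRVVGWPRMPP
EFMTLNCGIDYYTPDQPTNYEYSEEYTFTQHYQTWCIVIWYCPPTLVWTFLEAAHQQQEV
AYTANFEKYTTRHIYISVFYFLICWERHAKVAPYDFGDQGSDIWMDCMTIPAGFVKTNCV
YNPVIYIMMNKQFPICRKGTLCCGKFPKHYCEFSCTVWKTYWSQTCPV
>Sp_opsin_3_1
MNGTEGPNFHVPESNNVGQHRKPFSAPQYYLANVWVFGKTYHYFFQLIMHRFNQNFVGLI
ETMQHKYFTCPYYYILLNLAYEALDYVFGGFFELLRVSLKYFFVFDPTGCYAYGLFAHLG
GYIALISLVVAAIERYSHVLKHMMCYRSGEHAAFGWVAFTPVMARSCAHQILVGSSRIWP
EGAHCRCEDTYMQPKTWTINESFNISMFTWMVIIQLAVKIKCDGQLVCHYKQHAAAVQEL
ATQQKPEAEWTMAVIIMVIIMAQCWLSAAGQNQYCETCQGSDNIPTGMCIPAKFAKTSAV
YNPVIYIMMSKQFRKCMVVSHCCGGNFLGDDRCHTTVPHTNESQVASL
>Sp_opsin_3_2
MNGTEGPNFHVPESHNVGQHRKPFSKPQYYLANVHVFGKTYHYFFQLIMLRFNQNNVGLI
YTMQLKYDRCPYHYILLNLAWEALDYVFGAFFYLLRVSLKYHFVFDYIGCYAYDIFAHLG
GYAGLISLVVLAIERYEHVLKHMFQYRSGEFAAIGWVAVTPVMALSCAHQILVGSSGIWN
EGAHCRCGDTYMQPFEWTINESFIIYMFTWMVIIQLAVCFKCHGQWVCHYKQHTAAVQES
STQQKIEDPWTMAVIKMVINMAQCWLSAAGQNQYCETCYGSCNIFTGMTIPAKFCKTSAV
YNPVIYIMMSKQFRKCQVVTHCCGKNFLGDDRCQFNVPHTNEQQVASL
>Sp_opsin_4
MNYTEGPSFLVMFSNWTCTRRIPFVGPQYYLFCPWQRSMLYAVMFLRIDLGFKISQKTLY
EDVSHKQLRTFLNYWTWSEAVSKLFIWIGGFITTLYTSLHGTFVILWTGCNLYGFPATLG
LEWALWMLVVLANERYVVVTKMHSSFRFGMNYASAGPAFWWVAALAVAFPPLVGWSKGVW
EGFLCFCWEANYTAQEETAWLSRVIYMFNVHFVIKMPVIFVFYHQLGFTKKVSARQQQES
ATKKKARKGVTEMVITMVLADLFCFLPSAGQAFPKFTVQGSGFSPITTTEPAFFAKTSAI
YNPVIYIMMHKKFRNCPMITLCCGWNPLQDDNVSTTVSDKNTSQVSPD
>Sp_opsin_6
MNGTDQPNFYVDFSTKTCVFRSMVKAFQNYLMEMWQFSMPATWLMYCIMMGFRIDFLTYY
LTVQVHAPMDGFNYILKNLALADLNLVFERARHTLYTSHHGEFMSASTGCNFYGFFAHLG
CKIWMPTGVVSADERYVNSTLRMSDFVFMEKHAIMGHAFSWVMGWMCQVPNLVGWSDYIL
EGMQCSCGIDEYIMAEETNEFHFVPYTFVQHFIIPMGKIFFWYGQTVFCVKEMDAQRQPW
AWSLKAEAVKMYHVIIMAIIQLICWLPKAGVAWYIDTHQGQDFGPIFMHDPIFFNQTSAV
YNPVIYIMMNKQFTNCMVWTQCCCKNPPELDEAGTTVSKGETSGSAPI
>Sp_opsin_7
MRGNEPFNFYRPESVKMGDWRDPIEAPDCYLHNPWMFSILAAYMALWIMLGAPEDFLTLH
NVVQHKKLRTHEFYSLLWSAVAQDAMVQGGSTTTLYTTDHWYFVQGPTMCHWYKFFPTTR
CEIALKSLVELAIERYVVVCCVMPDFWFGENLVYMCVVFIAVWASCCAAPNLVIWSPYIP
EGMHCSCGGDYYTPHEETSEFSFVIYMFVMHFIIRNIVLFNHYGLEVFDVDEAAAHPNEF
AYTMEWEKPVTCFMIILVIALLGCWLPYVGVAFLIFTHQGEDFGPIFLFQPGFRGKTSAV
GNPVIYIMMGKQFTVCHEHKLCCLTNPLGFKEISSEAWKTERSQVAPN
>Sp_opsin_8
MNGTEGPNFYAGFSNKTPFVRSPWLAFQLYIQEEWIFSMLLDMMRLWIPLGFPIPFLRLY
VQVQNKKLRTPLNYHLLCLAPRDLFYSQGGFTTTHLALLHGYNQCGPNYCNLYGDFMTLG
EWIALLSLVVLAHERYLLVQPTMSNFRFGEFHYEFSVAFTAVQKMACAAPKCVQTSTYIC
EGMQSDCGIDYYTPHSETICESEVIYIFVVHQIIPEHWSFFCGGILVDTVKTAAAYQQES
LGTLKECKEVTRMIISPPYEKLICWLPQNCVAFYIFTHQHHDVRPRFMTIHNAFHKTSAV
YNPVIYIMMNKQFRNLMDYTLCCQKNPKGYKERSIMMEKTSWSTFSPH
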