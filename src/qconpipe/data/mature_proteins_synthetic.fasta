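>rbcL SYNTHETIC stand-in mature chain, average MW 52455.27 Da
YDDRIAKVCYLIHNHLDLMKARDHMKRHGDMLAEDMWKRGCPHLCWDRWEHKTNHPTSFK
MEKYHKYSACHMHMTCHWRVKWKGDKVFIKTCEFEKLVDRVKLVWAKWCWILTHIAIHKV
PRVEFHPNVECYFCYTWHNDWSKPMSTFLMVKDEMPCVGKKTLWKPSIKYPWDYYYNKIS
HVMYDVDHGFSFYMPTNVMWMCNDFEMVVKVHSKHHKAMVPEWTYGGDEKHFVHHEMGWW
RQEDFRRKRLMVNMRSCCCLLARKEPYEFHSKDFNDSHVKWWAERKSTERMVNSFREWFS
YTTWWVKNGAFDLSPASRQKMFTFDQTKATYKGIYEHLVTMAHPHSEDQGFELMHIEQNG
DCHCEICWKTRIQCKWERWLEHNQICLVPCRMFQCFLWAREAAGVCWCDNFQLWKIAMGI
ESVGWCHW
>RBCS SYNTHETIC stand-in mature chain, average MW 16268.30 Da
NYHHLTDLHSYAQRTMMQNIRYDLMEINTTRHSDVFRTFLCWWMSPTNVEFAPAPDNYGS
DHLMIHGCQRVVWAPNWVIMFYRWPDDYEKPMQNPSKSSPMCQGDHWGSQLVDTRMQHFT
PSWHMNYLLFCVWY
>PGK1 SYNTHETIC stand-in mature chain, average MW 42779.98 Da
YVAVIVKHWCNPTLTNNEYSKTPTTPVMWNRHVATPWRGFYDICPLSAMKGKKELTMSKF
GREVKIKGPTKIIKHGHCRHLRTDLYWRTKMDAMFWIHNVRDEAEPPCWMGQDGIGIDGT
GCNIQNMVEKYKLPNINIHFIGWWWKSKHEIDRMWYRKLERNEHAQTCGHRYAMMHRYHD
SELEEIEMKTQLSPPENAKYLRKEMWVMHPHKRMGDQQMWYIGNTSMEIGVEPYVSKPVF
GIEFQTRVTVLNWCHVAGSFLQYEKTWKVSWSQVTYANSWFRMAQIVTQSDWCAKCWCLW
IAITGHYDWLEPCHARFRGVLGLPTPKGRYGLFVFAMGAQVEEIGEQQKFPDYQFQNIIR
>GAP3 SYNTHETIC stand-in mature chain, average MW 38054.53 Da
TWWHRYACWGNEGMYHIFWTMIWFHPFWRNCHLEITSIDYHFQAFMPNAHVQSNDWCDSR
GIYINHQHWLQQMFGQEHYFCMIPMNEESWHIFNWRYVINQWNAQGVEYPQMVPPDLIMG
QFTCLQETREPMYISNAGNLENFGLDRAGDPWQCIGFGSETYPANDLWDHIQAMCFPWAR
CMMLVSLLQDEEAHVNAPDPMRPPPPLDYCSNFHWRAENHNTSSTWCIWCVHFAHQYAFC
QQNACQVMGCTQGPKHLCNFDQADLETPNMPASKNWYYQPTRGPPEHFTFWVMIGAMECY
SFNHRVQHGTYAKQVDGRY
>TPI1 SYNTHETIC stand-in mature chain, average MW 27599.99 Da
WRVNMNCKWKSHNDREICMVFPGTKIWGNYCLSVTKGYNYWVEKCWPGKGVGVSSLPPKA
NIFDDMLIGMDSMVNVRGCPFTCMSRNLVLIWKKNFEKYRNMLKHPCGWWSSRLGGWPPR
PMSTVCFNKEDIWYYPSMRCRKRTDMPVKAMMMDPRAGGTGCPDISPESYQPRGQSHPWK
DFPPSCDAHNRHCCVKSRDEYAGVHPAIAQPCVGPFCYILLQQVINMAHKHAWGMFFR
>FBA3 SYNTHETIC stand-in mature chain, average MW 38257.41 Da
PGYYSGTRTRYVLGQTTLTSELTWGDSRMRTPYAKRKVVSTKKHVSFTWTFAIDAYIRLP
FPWGVLSDSIQWGQCKEVKYMFHAVQTRCFICMTEMWLCNHAIRLQGNGYNMPKDEQGPN
TQVRVCGPCWRWSKCSRHWPKSRRDCDPIDSQMAECPNIPQQPVGWRPQNAPSVWIIMRE
RDFCKIDDIFYGFWCQITNFERHNDLVNAELHIKYGITKQMQIVWFCHYFKIHEKQSRHT
NFLYWMNFDVVKQKMDGVKQSTPHPKCNECNWYDYGCRWDRIANPFIPQWNLWSQHIYLK
APNCYSDIRYKDGGWTDFW
>FBP1 SYNTHETIC stand-in mature chain, average MW 44160.01 Da
VKWRIHFDTYEVGKTRKKKWTDTNEANLINICCFMKDHIYDDKGHHYNDGRRAFAFGFHM
VVGNYMVGHAAYYLTHPKSRAHDKFIMYDEYNTPVVDYSCDFHGLTYKPMIRPHTCKYDP
NPMIEPDPRCWQYEWNHRNFDSLWHSSHGKMKTWSRDKNYAITLFLWKPPWRKYRDGIGH
CSYGFSSICTMGSVNDHGDEVDCHWHTNMGSAYYRRMNAARYQRCIGYSRWPLRIPNASM
NFWQDARVEYYTRMQLWFWGDLHAHQEVYPCGKRTHMWYTTGFTVYVAGYDEHNVGHHYP
ERWDCYNLSGNNSQGFHHDIVGLYYHWDSNDIEASDMDMKYDHINPTGFFPTDKKLLTRA
PREHQRY
>SBP1 SYNTHETIC stand-in mature chain, average MW 34500.01 Da
FATFVSNMKGTYCKDLLAKVKYKEGIFIQDKNDAGCQQNSWYNYIYMEGVFGGPEPNVNF
YGFKASEITQCQWSPFFAIWIMPDVYPQDYGWQHPDMRDRSMIESRGCQKAWRFDWQCSH
DYGYILQCVSSHTKMKEVVHRDDWWWLNMNQYGSYQGVDWQHDAPQMDHDTPYFECMSYW
ADMTVKVIVLHITRHFHSFMDSRLLCYWGFTEQVTHRSQMVYKIYRWLGNHSMQCPPNRR
FLIDCLPFVYAEYFCWPAVCRMPECFKCFILEWDKQDWNSVVFCW
>TRK1 SYNTHETIC stand-in mature chain, average MW 73139.99 Da
HHHRTDSEPARRYTWYPLFINKALWDVPRRYEVVFYIDMGLTAFYVLFYREAWPAEIRNE
SGPMIWVWGRPMMECPSPAKKCAHPHKGTNCIEHSMSTITILKGRWCRRPHMWACKDPHR
MNREVSCFVYMHKFNCTCRMPSYMGPASFTENSTGKIFMVDCDAHNVRSTRNCKCSKKIT
RWDPNDDWCSHVEGNERCVMNNYPMSCHRGGYMMMAFHEHTCKMRKRTPKWECWWHCDGP
PSRVMPWIPCPNERKPRWELTLVWHHKKVTTGCYTTGNWVAHEDLLKPVGTENVMADKGM
KWQLNKGLLGIEKAIFFRCLVRMSKWPALRWIRLVCTDAIVPCLVSNSQEMKWDPNPLMI
NEYVWFNRLCRNRPHSEDYKRPHKCNLGSFPGQECGMYQNYFNISMFHHNHMAQPCNTQH
CHQYRFMVSTISLWPDVWDDDKRWPWDSLWFMWNIGVCCIWLGCLIPKERPCACWSATYK
AHGEDCVMPLITQTWIFFGHPPLHRYKTICKYRDPSIVRLMGTSIWGCVKGNRPPWPGRP
RNHMHNMCWCTANPSVNNWCLFEQWVEEKQTQLKYHWNNGCLDAAPPCGKVEPCSTYADM
MYAVFDRGFDHDANEY
>RPE1 SYNTHETIC stand-in mature chain, average MW 27600.01 Da
SWMYDQTASMDTSENQDEINRFYCDQFEQIFATHFQRKGTPFWFWRNDSCTEAPHLPQAW
CIYHADFRRGVSQTRGNHMDQDASHLHEWPVAMDLVDHSMFHMEFDYTTRCFPWNNQINI
YTGVFFMKDLTRINGWALPCHWGLVANERDGRNWSAHAILGCYNWCVFPKCNLAPNRTWV
MSSKLCLMSSCEVWYMESGMMHCAAADQIYEKRLRFTWAMEMCCERCPNYY
>RPI1 SYNTHETIC stand-in mature chain, average MW 27599.98 Da
WTWYMPPQFGESNFERHIPHTTLIAVEDEGPQGPAYKARSKMMQDSGSQGHWSMTDTAGL
FNRNMTMFHWAQYKGACDSGKFRDPLKHTKALRFESHHCFSNPAIWSTGIKWEFMFHLKC
TLFDWACKEMRTLMCNVTWHSPMTHTTMVIGMWKQFLSDGFKHNEDMWEICQAYTRKIHR
RVVSTNVNSCVWTEEEDNNDICVWHQELYDFTHINWRYPYYPWQANSAYRV
>PRK1 SYNTHETIC stand-in mature chain, average MW 38333.34 Da
LGRSTEPNDLFHSFPCCNTKKARFCNKSHCDPGWDKHHHSDHMSTICFPVMHILEPTEGF
YAPTGKEWVATDMFGANIHWMKMEIKFCKRVYRDFYVFPANVYKTFWHFWAMFIHEDRPH
AGTGTYLIALNCIIHCTIKDYGGRLVKEIEAMWIEHHIWCECMICNRNRDEEEYRADRSA
CSIMPTKAFWWLATCYIRWTMSVDGCMIHILIYPKVLKIPLMCFIHKLAIDGAMEFPAGT
HCKPSMEFAGKRDTHCNQHMVEFRMCHAAVRKPAHDWHSSGKEKFDHERIDRTRAIIGYA
KTWCLMKIMMPMKDQIWDTGHWHM
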