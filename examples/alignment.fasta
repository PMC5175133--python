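>c0_l0
DPQVNSTFLTPVWCLTDSDLTHHTHGYKLQNNMYTPPIKCNFGEIPFAKADMYSTVTPKI
GCLFYWCEKQVCRILSPTQLMGYVVLWCTPAHLCDMTMPVMITIDCIINVCESYLSNQLN
KWKPMQAENKIFRSTKVYYFVGAHLVCQMDTNVWPWYNMDNESWFNAENVYTNNCQRKQG
RAYNQISILDKSCAEPTAHDGPHQFLCMNVYHMNGQVIWHHKSWVEIWHAFSYNSDTKTT
YAVPLYYGCRFPVETIDEKHHWVNYHDDCHFKHYIMYMVVSVNNTGWVIMRVRCDWEMMY
>c0_l1
DPQVNSTFLTPVWCLTDSDLTHHTHGYKLQNNMYTPPTKCNFGEIPFAKADMYSTVFPKI
GLSTYACEKGVCRIGSPTQEMWYYVLWCRPAHLCDMTMPVQITCDCIINVCEFYLSNQIN
DWKPMQAENKIFHKTKVYYFVGAHLVCQMDRNLWPWYNMDNPSWFNAENVYTNNCQRKQG
RAYNNISILDKSCAEITAHDGPHQFLCMNKYHMNGQVIWHHKSWVEIWHAFSRESDDKTT
YAVPLYYGCRFFVETIDEKHHWVNYHDGCHFKHYIMYMRVSVNLTGWVIMRVRADKEMMY
>c1_l0
DPQGNSTFMTPEWCGTQPFLTHGLHGYKLQQHMYTEPIKCNFGEIPFAKAITYDTVTWKM
GLLTYAKETQVCRLLSPKQEMVYVVKPIRQAHLPYMSMIVQITIDCFYDVCESYMSNQIL
KCAPMQAKAKYFRFTTCYRFEGRHLVCQMVTNRWLWYNMDNESWFNRTPVKTNNCQRKQA
RNYNNIRILIKSKMEITAHSGPHQELCMNKYHKNHGDIWHHKSWVEIWHAFCRGSYTKGI
YIVYLYFGWRFFVWTIKEKDAWVNYHDGYHFKHYTMYMTVSVPNTQRVLMRVRCTKEMMY
>c1_l1
APQLNSTFMTPVWCGTQPDLTHGLHGYKNQQHMYDEPIKCNFGEIPFAKAITYDTVTIKM
GLLTYAKEYQVCRLLSQKQEMVYVVKPIRQAHLPYMTMIVQQTIDCFIDVEESYMSNQIL
CCAPMQAKAKYFRKTTCYRFRGRHLVCQMVTNRWLWYNMDNESWFNETPVKTNNCQRKQG
RNYNNISILIKSKMEITAHSGPHQELCMNKYHMNHQDIWHHKSWVEEWHAFERGSYTKTI
YIVILYFGWRFFVWTSKEKDAWVNYHDGYHFKHFTMYMTVSLPNTQRVLMSVRQTKEMMY
>c2_l0
DPNGGYTYLTPVWTGTQYDLTHGLCGYELRQHEYTKPIKCNFGVRPFAKAITYSTVKHID
GLLTTAKEYQACRLDSPKGEMKYVVKPIRQAHLPQMTVSVQVTIDCFIRPCESGMFNQSL
KCAPMQAKLKCVHKYWTYRYRGGLLVCEMVRNRWLIYNMWNESWDYEGPYKTNNQQRKQG
RNYKNTSKLGKKFMLIMAGSGPHQILCMNATHMSCQRIWHYQTWVFIWPAFGDGPKFKES
NYVWLYTGTRFFKQTEWEIDPWVPYHDGYHFYHKVMYMTVSVPNTSWVDIRNFCHVEMMT
>c2_l1
DPNGGYTYLTPVWTGTQYDLTHGLCGYERRQHEYTKDIKCNFGVRPFAKAITYDTVKGID
GLLTTAKEYQACRLHSPKGEMVCVVKPIRQAHLPIMTVSVQVTIDCFIRPCESYMFNQSL
KCAPMQAKLKEVHKYWTYRYRGGLLVCEMVRNRWLVYNMWNESWDYEGPYKTNNQQRKQG
RNYKNISKLGKKFMLIMAGSGPHQILCMNATHMSYYRIWHYDGWVFIYHAFGDGPYFKTS
NYVWLYTGNRFLKQTEWEKDPWVEYHDGYHFYHKIMYMTVSVPNTSWVDIRNFCHVEMMT
>c3_l0
DPNGGMCYDTPVRTGTNIHLTHGLCAYEHYQHEQTKKIISNFGGRPDAKALTMDTVKGID
GGLTTAWEYQHNREGEPKGMMVYVVHPCEQADLNSMTQSVQVSGDCEIRPFDSCHFNDSL
KCAPMGPKHKEVHKDYTFRYRGGLTWCEWNNTRWLSPYMANEHWDYKGPYKTNNQQMVEG
RNYKNICKTGKWFMFIMAGSFPHSPLIPNATHMSYPRCPHYKNWVFIVEAFGDVPQFLTS
NYVWLYAGQYFFKQTEWEEDDWVCYHDFYRFYHKVFYMTVSVPNWSTVDLANMCHVFMPT
>c3_l1
DPNGGMCYDTPVRTGTQYHLTHGLCGYEHYQHEQTKKIKSNFGGRPDRKALHRDTVKGID
GGLTTAWEYQHNREQEPKGEMIYVVHPCEQADLPSMTQSVQVSGDCEIRPFDRCHFNDSL
KCAPMNPKHKEVHKDYTFRYRGGLTWCEWNNTRWLSPYFANEMWDYEGPYKTNNQMMFEG
RNYKNICKTGKWFMFIMWGCFPHSPLIPNATHMIYPRCPHYKNWVFIVEAFGDVPQPETS
NYDWLYAGQGFFKQTEWEEDDFVCYHDFYRFYHKVFYMTVSVPNWSTVDSANMCHVFMPT
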