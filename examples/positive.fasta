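>pos0000
IRNHWTIYGSQKAVNKIPILICHTSQKYTGMWRIKLVRKKDLGDDGRFMNYKRAPYCVEQ
ACEVRQPHLKWKRIWTYGTKLMDVNDRDIQKCPIIEFYNNRIENK
>pos0001
KDKCVIRNKHAQDGWIIQHIHRCIYPKHAVWYKNHSNHHIQRDWRSFERWHDHTSGELHT
KGKGRYNGSIDEISGRDTRDCHFPKNHYDQMYWKKIFQVKVGHWWLMIAIYLSERNYHKH
RCRSHIHTEVDASCMLVQYQHWCQDFILCKMHKRFH
>pos0002
HAWLHVADAAANRIWRYRLCDHEPCMIICRRHIQEPHRPHHKHRRLGLRMADITKPMCKK
KVHYKKRKCMDWHWLRLGYPKWMKFHSEKPKKASCKDHRWAHQIYEERRWCAEWKKHFDR
CRLFGCTNRMCRVHKYPEFHWSAMFHLFQAAHDT
>pos0003
RMRAGLSNHHTMTDSCIKCWKCQHNQYNPYHHRPHWYYRSVNVMHLEYEHESRTWRNRTE
GNKWHCHFKDPIGVYQDLRKFHVCCRSPVLPKRAKIDKREYF
>pos0004
ALCHSNVKDCLWYRCFPNVKHDRVREPVKAHQEIYEKPGSFNAYLGEAHTHWYNDHRIPQ
FHQLLDVARHRHSPYRVIRQGRMVLTHIMCKVQWWDHRKRKFHMVALMVCKRFQHLMDML
GARKLIIMMINIKIACVKEPTIK
>pos0005
VWSKICRFRTLNPHHHPTRPDIKQSKSKHDHKRTKHLIGRHRPHSHTQDKFKCDMRFMRT
KYYSIFFVCKTGEGRPDENMRGMSYRTFKYPEIFSEKKLTCFFKVRKHSPRVCSYLCDVF
RRKGDHPSKDSLKRAFAHKFACIKFLPHLFII
>pos0006
RHQHVENGHIFLVYDCIWRIWVKWSRRWRQKYHTGGGVRHEREVEQGPVSPLKRRQKRIH
CFYPIWCHKGSHKYLGNTICKSEHFVTEEGRDMRWYKTYYTPDMASFKESKICR
>pos0007
AHSKHTGYHGVAVMSKHKFAHPGDRATAGKHLRLKPHKKHMYPDHLDPQPMHIHKTIRKK
WHVDRITDSSYRFRHYSMDINWEHRYYHRECPKNIAFASDECSNFGFEKWWYDRIMHQHV
GIRDCDQYKKDDGL
>pos0008
HNVDEFSKTLFPFSFGTSPKQGAIPFRTIHESIYKMHLRHPYIFWCYWILENATDWGIAI
CWSYKPLYMSHRRKGESWFMPDTFQMRNECQVKVYMHFNVALYR
>pos0009
RHARSEDFMMIYRLFCKVRVHIKGPEMKHCHKHIHKGDDKRIGPHISKHHNYMSAYLSYN
TCTEAHKPFNAYVKHKWQRQYDVHCHDRQKSHLMKFRGCHIRMW
>pos0010
HVAFRHWDDHRTHIRPMQMDDKAIKYNELKRRHSLAKEPRPHGDHMCSKCHFHIHCTQNR
PMGMLSSQKDVLYDCNAYARRPNRVVKCRHKHEEQMFRSQNVHQNNIHCKRNWDLCW
>pos0011
HHRTYKGWNVFSTYIKQHRWMNHGGHRRGKYKKTRKSHAHVDSLGHVSPRTIIGAMAPNT
HRLFPNYRRHWAKVCLRCHQHRIQLDMMKTNQEKHRDHKKRGHDRHHHKSPLVPYQCRKS
TMQ
>pos0012
IWACNKHTRVWRFLQRKDDKVVLNTMNDLTLGDTGVDIVPAFRTNECYSTQHDSMCSLQA
PIKNPSSFYVFQKVLMQCIEDEYLNQARTIRHHHIRTQIYFVTRWAVMTESTHGRRAQKG
HSDMKKAAEWRHHLTKEVHSYRRLNLACQFKYWWN
>pos0013
ILNKECDQRCKHRITGFSKRQRQVEKCEFEHVSKTSGKMSHEGYHAPHRPECAFGDNFHL
HREYVIGAKDNHSHRQEAEMSQANHPYTRNKVFHQDHDARRTVDMQKRVCEHEDDTPLNY
TKNKFTHGMYF
>pos0014
KFHRYTWVCAFHRGKEMRHRQQRHRWHCQSAPCHMDQRGNRHQVRFTQGEATWRIQGNDH
MNWDSPKFEQHINFPHKKKHKKNITWHATCMHHWHGMTPKHPIRPSIHRNR
>pos0015
DKPQDMHMLMNKQGHKKWIVRMTHCHCHMGFRAGCIYGHEWCLSVEYQCWRKQKTEINRE
KKSFTMNDVIKWLKARLIHDDQYECAKDFKKNRKTHNELRHHAKRPRMWIHVFIYWKKSI
AFYTTQHPWNHHHVARKHFWKYKYNHSHTQHM
>pos0016
CYDLRRHQHLHRHRPHHTSWQVDHREQGSQMTGVKREPTTHKKVLKYIQVSDYALREHWK
QRKYRRLERESSDIHHNYDTAYNKHHWHCHWPEKWIPNCNKVHRKGINSWKALKRGNYKV
KFAFFAGKPRMLGGHNQGECWHRMH
>pos0017
SFDLRDMHTCFHLNQCKWKDQKSEWNVHIMLNGSEVKVQTKRHFWDHSPHWQWWIWRHNQ
VQKRKREHGSVCITRHQMVVFSHDREHHYYWDSRKFMDKVYKLRCHKSNRHYSP
>pos0018
FTHQYPERMKHPTFKYIPWYSKRSWAINWWYAGTLCHAEPVHHRWHRGNVEHKMCGEPQT
LFYGGRFFCYARSTIHNWERQRWMVFGQQFVHRTFHSTEAWLRRWALWGEKHYPIGKQCN
CEAMQHNHMRPTHDTAWGAANRSKRQHLRYCQSCKR
>pos0019
PLYSLLHSRYYRHPHQMQVKVIKHHWNCWIKHCGHHCHIGHWCHHTKCQAEQRTYVEQFY
RYPFPNKCHAHSCHQDFPAAGTLSWTKNHGSKHYCQIHLPECKLKRVKKKQKSPIFVRVP
REKFTEDHCVVWTYYDRLCTQLDHTK
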