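>neg0000
NTGQLVNYFDHSMWYWENRWDPCRNDDMLMYYGCGTGDPQECEFINWHPQGNYYKTHTIS
CFPFGQGHTDATWQPVMDIKVPCQTCWCQIMEEGSTSHHKEIMGECLMHALYNLL
>neg0001
HNEVLQCIEEPQPHVSNIRGFAREHLLTDPMFHIDCEKVGTVFTLMSLPDCTMCSSGRYN
VDCIDYELCASQITRMSPCGMHNQHNGQAYMI
>neg0002
EWLLDLGKRRFLVNGEEHESYYRMTKAYDCSMPPKCMYMVVQFWTSCVPPCSSGDQEKRL
SEVNMDNIWDMLWVLVNDCKWSWYRIGSTYPVGGL
>neg0003
EVTWEQADMRQDHLANLNYLYNLETHGIMISFFPAITWQEIKVFRKRQVQGKKEWFHYQT
AQKYVPWRDNWDPCKRKWHTAIVRSKNQKPMIMNPRQWYARVNDYSHHCHLGCFA
>neg0004
PTTHNPDPLNVGCLCYTELWASKDVQKFVEPPHYYTFYWYVNDIKNSSHSEKTQAWTLKR
CIIVFDNIDNMPRQTGELFFQFVNRMYNTTHEMLSIMDIGIYTLIGKYFTPWRFYWDICM
WSQLEDMHTRREPQQMNRYAFSNEFRK
>neg0005
SYITLSIDHPYHMWRGPICKYQPNVKAIAMVILTSGYRDEFYSYTMVGQQSVWDAKSIYY
NVRHSRTCGLSYAELIGLMTSLHLQVHGCCMFYMRTDKYECFIWWKNITMMS
>neg0006
PGHQCTPGSKFSTDDSWSQDEETYEKVYLAQSDSFCRDMTPGSIGTGGIAPDHSDITPCF
RSAIKLQTYQITWMKPENMTCCILNVAWVYGSRPFNQTNMWLQSQMGETRPWSWSKRSKG
LCISPTIYPTDGCAFVKCCQQIYAF
>neg0007
NGTDIQDFHPLYWLFGQDCGNYHCSVIMQQRQAHCCGTFLQLQWWGKHTGIDENATFGAY
YRRAKFQSLKNDANRMPFPDAGDNVFRMLNKMFVMQELCALVNAIGPGQRIKVFWGQHYE
PKENVF
>neg0008
TKTKARWRSVVNGSWIYMDPNQSVGACCNIGLKGAIYARLHYVPRKVHYFYYTFCTGKPQ
TNNNKQYRENDYWSVGCHHGPFRWPLHNHRQDKCFTMPVRGEQHNSYVGLKYQYTRSYAG
SCGERWREVNPKKYFRGGWKLTIRIPKNN
>neg0009
RGYMSFHMKFCHSNQKWMDYCTKIGSQRDTWAWDKNSVEADAELDMQNLNSECCNQFRWI
RKNLEVDAAVPIIKLFLKRQDQD
>neg0010
SFKDPTVRWQNFMITEQGSHGGSKRLIYTCHFFKLLLNMQCHFFNPPFWAYWKFAAAECA
GLTILMFCQWEPFKAVCLVKSRLRPWDFDRCVDRINYIMESRIQNCWETWWKGFMMRKCY
GSWSKENCSQRHKFDKYRAKNSWKYLYEFVWRDMQ
>neg0011
RPCWYPNFMSTWGLKFHIADPNNHLIRAWLQVFYMHDWLNRATYSCPGAKAPERNQCGCI
SHRYISADTIIFQTWASGWARQCRHLRYFKAACILIMAEQFGCIRHVKHAKMSHPIPCAR
HVPGERFKLYQ
>neg0012
GKPTWPESKIIIPYDPTRELAGGSYSQSRPSCKYCWYPLKVMHDYMAHKTVRWAHCYVMY
DGTAQLARHAYGMERSWHHRCCVFGAGGHMAYPWEMSTPNMDRFSLFEMYYVATIFHIKL
LKGCCAAVMMGKQVIDSWKCGWKPPVDKQKVTKIVIADLW
>neg0013
VNPVCRSLRKNSAYSTKQYQHLKFVYRRNMYHCCFTQHFRMGHWHLAELYGTMAVQPRCL
PWRLYFVTAEWPQSGWIWTKPYIYHEDWYDSCADYATQRATSITMFRRTGQDTDMVPNRK
EWDPKYPGRRWNEARQGDHTPCNPSQCFLDYNLSPWDPP
>neg0014
AGDNVWAVNHWRCAWRACYCDHGMAAQRFNYFVSPSRQDRDISAHERFEMFEGLWFKLDA
TLMVLAMKIYGNPSSSKINMMLDDRFNTCKPFHSFALDCNWFGGDMPRYGIKTRHFWCIM
WNAQYVNMVDQIKRVW
>neg0015
TNVRVENHVSAAFNEDPIPCGYEKHPCVAPKHWRYWAEWIDDCFEFVDLHSCTPPGGENH
NWSLAQHHYFKHARERANQVCQTDCAEYMNMCTIPFHYKSPTQCQNDQ
>neg0016
DSEQFDITWVHGNDCGANWEGKYEQIWYNCYIMLLGQECAAPSEACRSACQNECWQVKIE
DNCLRDCLNAWINYGQPFVSFCAMAFICY
>neg0017
TAEPHDRDPFCVCQKFVMRGKTEGYGFREHRGRNTVWQSFLSPQQWPLANIAEPFQLSCD
KTVIMTYTMRREQEKKTWLKRFCKFCGVINGIWTQMRPYWNNKWIFVMQSTWREWGRSLM
FFRSNPYDLYEYRTRGENVGVCIRANYCAVTCRK
>neg0018
YFGDIRGPWREGKPVLHTFTYMQDMTFRNYVGDMEDPIQHDNFWEHGGYQIEWRWWEWPF
KITTPTWSPYTDTYTHHQRQGTDELITCDQMCSVWKPIFGEVPCNVKTCHYTQGSQQSDV
RCRNGVRSVNMKIQTIKRRCDSQAFWNPIPCRN
>neg0019
SFFFRMEAQAWHKCFERCGFEDSAEQDIWILCNITRCWRGFHIYYWKEKLTMGCFKHKQC
FKQLFEPITHYHYVTVPRQK
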