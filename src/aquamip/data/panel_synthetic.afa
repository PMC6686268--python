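; synthetic reference panel rendered from aquamip.synthetic templates
>SYN-PIP1-1 subfamily=PIP subgroup=PIP1 synthetic=true
TEPQNNGKKSKTSKNGGPGEPHSETPRTDTTTDDHSKQSDSDHKSFFVLLFFFVIFLVVF
VIVLLLVINKQNPHDDPQQKVFFIIVLFLVFVIFFVVLVILVLSNTKRPNPARPGTDPK-
-----------FVFLVFLLLIFLLFIVFLVVIFVHQNRQPSDVVFLFLFIFFVFFILLIL
ILVLIHPSQPPEGVVVVIFFLLLFLFLHLIIFILLLERTRNPAKQTRGDQSRATNRELFL
FIVLLLFIFIFVIFLILVIIGHGGFKWPDTGQDQTE
>SYN-PIP1-2 subfamily=PIP subgroup=PIP1 synthetic=true
TEPQNNGKKSKTSKNGGPGEPHRPTPRTDTTTDDHSKQSDSDHKSFFFLLFFFVIFLVVF
VLVLLLVINKQNPHDDPHQKVFFIILLFLVFVIFFVVLVFLVLSNTKRPNPAEPGTPPK-
-----------FVFLVFLLLIFLVFIVFLFVIFVHQNRQSSDVVLLFLFIFFVFFILVIL
IIFLIHPSQPPEGVVVVIFFLFLFLFLHLIVFILLLERTRNPAKQTRGDQSRATNRELFL
FIVLLLFIFIIVIFLILVIIGHQGFKWPDTGQDQTE
>SYN-PIP2-1 subfamily=PIP subgroup=PIP2 synthetic=true
-------------------------EQKTESETPSEEGPPRQNRELLLILIILFFILFIF
FFFFFLIVDRSPHSDNSDKQVVLLIIIVIILVLVFVIILLLFLSQKSTSNPANKDRDQQ-
-----------VIFVVIVLVVIFIVFIIIFFFFLNSQSQKPHFIFIFIIFLFLFIILLLF
VLFVIEGNTETERILVFIIIIFLILLIHVIILLFVVHQGENPAGHTRQKTSSATNDQFFF
LIIIIFFFLVVLIIIVIVLLRGPRFPWRKEKRRHRH
>SYN-PIP2-2 subfamily=PIP subgroup=PIP2 synthetic=true
-------------------------EQKTESETPSEEGQPRQNRELLLILIILFFILFFF
FFFFFLIVDRSPRPDNHDKQVVLLIIIVIILVLVFVIILLLFVSQKSTSNPANNDRDQQ-
-----------VIFVVIVLVVIFIVFIIVFFFILNSQSQKKHFIFIIIIFFFLFIFLLLF
VLFVIQKNTETERILVFIIIIFLILLIHVIILLFVVHQGENPAGHTRQKTSSATNDQFFF
LILIIVIFLVVLIIIVIVLFRGPRFPWRKEKRSHRH
>SYN-TIP1-1 subfamily=TIP subgroup=TIP1 synthetic=true
-------------------------------SKNQRPRPNESDKSFIVVLVVFIVLVFLV
FFVLFILVQPKGKTQEGSRGLIVVIVIFFVVFFVHFFFLIIFFRPSNTHNPANDTDGQET
NNS--------VIFLILILLILFVLFLLLVVVFFQEGGFKGGVIFFIVFLFFIIVVVFLF
LFIVVQPKTENNSILILFVLILLVIVFIIFVLIVFVQRRENPAHKAVTGQAHSGPKSIFV
LVILILVFFFVILFFFVLLVEPHTYKWDNKHKRNES
>SYN-TIP1-2 subfamily=TIP subgroup=TIP1 synthetic=true
-------------------------------SKNQKPRPNESDKSLIVVLLVFIVFVFLV
FFVLFFLVQPKGKTQEGSRGLIVVIVIFFIVFFVHFFFLIIFFRPSNTHNPANDTDGQET
NNS--------VIFLILILLILFVLFLLLVLLFFQEGGFKGGVIFFIVFLFFIIVVVFLI
LFIVVQPKTENNSILVLFFLILLVIVFIIIVLIVFIQRRHNPAHKAVTGQAHSGPKSIFV
LVILILVFFFVILFFFVLLVEPHTYKWDNKHERNES
>SYN-TIP2-1 subfamily=TIP subgroup=TIP2 synthetic=true
-------------------------------EGENHKHETHSGPDLFLIIILFFFFLFII
VLFLIVIIPRGEHEKPRETRIVLVFIVLVLFIFIHILLLLVFIHSPKPTNPANETTHDHN
EHP--------VVVLLLVVLLVFVVLFIVVVFLLQDNQFGSEILLVFLIIVFLLIIFVVV
VLVLLSKKEPRRNIVFFVIVFFLIFLFILFLVLVIVSRQHNPAPKGRTSESKAGDTPFLV
FVVVVFILLVIIIVIVVFIFNGTEYKWERGDQPEGD
>SYN-TIP2-2 subfamily=TIP subgroup=TIP2 synthetic=true
-------------------------------EQENHKHETHSGPDLFLVIILFFFFLFII
LLFLIVIIPRGEHEKETETRLVLVVIVLVLFIFIHILLLLVFIHSPKPTNPANETTHDHN
EGP--------VVVLLLIVLLVFVVLFIVVIFLLSDKQFKSEILLVFLIIVFLIIIFVVV
VLVLLSKKEPRRNIVFFVIVIFLIFLFILFLVLVFVSRQHNPAPKGRTSESKAGDTPFLV
FLVVVFILLVIIIVIVVFIFNGTEYKWERGDQPEGD
>SYN-NIP1-1 subfamily=NIP subgroup=NIP1 synthetic=true
-------------------------ENNKKQHNTKSNNDHGRGSDLIILILVLIVFFVFI
VFVLVFIISNQPSTRSSRGSFIIVLFFFVIILLFWFIVLVIFIGHPRERNPARGSRHENS
EKPEDES----IIFFVFVFVLVLFVILLVIVFLFERGNFGQQFFVFLVLVLFFIFFIVIF
FVLFVSRDQRQRTFLVLVIVVFLLIIVVFVLLLVVVGSEPNPATSARDTGSEAKKSSIFV
LLVVLLIVIIIIFVLVLVIFNREDYPINGDDSDSPR
>SYN-NIP1-2 subfamily=NIP subgroup=NIP1 synthetic=true
-------------------------DNNTKQHKTKRNNDHGDGSDLIILIIVLIVIFVFI
VFVLVFIISNSKSTGSSRGSFIIVLFFFVIFLLFWFIVLVIFFHRPRETNPARGSRHENS
EKPGDES----IIFFVFVFVLVLFVILLVIVFLFERGNFGEQFFVFLVLVVFFILFLVIF
FVLFVSRDQNQRTVLVLVIVVFLLIIVVFVLLLVVVGSEPNPANSARDTGSEAKKSSIFV
FLVVLLIVIIIIFVLVIVIFNREDYPINGDDSDSPR
>SYN-NIP2-1 subfamily=NIP subgroup=NIP2 synthetic=true
-------------------------NQGTQHTSNTKETNNKPSGTVLFFFFFVIILLFVV
FVVFVIFFQTKPQDRKGEHGLFLVVLIVVFVIVVGIVFIILVVQQENPHNPAQHPQSTPR
PSSEGGKREQRLIFLFFFIIIVFIIFIVIIIIVFTPPPLPSHFVFLILIIVVVILLIVVV
ILVVFRDRKTRHEILVIIIVVLIILILSLLVIFIFIRSSNNPVEKGRQSRTSAEHQTLFF
LFIFVFIFIVFFFILFFIVLEKTGYPFDHGPPEQEH
>SYN-NIP2-2 subfamily=NIP subgroup=NIP2 synthetic=true
-------------------------NQGTQHTSNTKETNNKPSGQVLVFFFFVIILLFVV
FVVFVIFFQTKPQDRKGEHGLFLVVLIVVFVIVVGIVFVILVVQQENPHNPAPDPQSTPR
PSSEGGKREQRLIFLVFFIIIVFIFFIVIIIIVVTPPPLPGHFIFLILIIVVVIVLIVVV
ILVVFRDRKTRHEIIVLIIVVLFILIVSLLVIFILIRDSNNPVEKGRGGRTPAEHQTLFI
LFIFVFIFIVFFFILFFIVLEKTGYGFDHGPPEQEH
>SYN-SIP1-1 subfamily=SIP subgroup=SIP1 synthetic=true
-----------------------------------TEPGTSQPEQVVVLLVLIVFVLILI
LLVVVFLLQNSTRNHPPHKEFIFVIIVIVLFFLLVVFIILLVFTSPNKENPTQRQNE---
-----------VVVVLFFIFLLVLVLFFLFIVLLDRQTFDKDIIFLIILLLFFLFFLVVF
FVFVLGKTHTRHPVILLFLIVILFIFITFIIFLFFLDTHRNPAENPNQTPASADQPGFVI
VVFILILVFFIVIFLIVVIFQNQKYSWKQSEETQPQ
>SYN-SIP2-1 subfamily=SIP subgroup=SIP2 synthetic=true
-----------------------------------NQDSQDKDQNFFFIVIVILIIVIVV
LILFVLVLTKQKHGEGRSKHLVIIVFLLFVIVVFFVVIVLVFLPSRHTSNPLTPPGE---
-----------LILVFIFILFFVFIFVIFIFFIFTDHDFKDNFLIIIIFVVIFLFVLVLL
IVLLLTDPQRDEPIILIFFVVFFVFLIKLVIILVFIEKPSNPAGQGSQRQVTADQRTFVL
IIVVIIIVILFFFLFLLLFIGNEQYPWHRSHTNEHS
>SYN-XIP1-1 subfamily=XIP subgroup=XIP1 synthetic=true
---------------------TRGTSHGDHRDSHSRTQTRRNGRKVIIILLVLLIVIVIV
IFVVVIFLDRRHDPNQDGSHIIVVFVLVLLFVFVVVFILFVILPPEGHKSPIKEHTTSST
NSGNG------VFIVILFLILLLVLILILLLVIIGKKPYRRHVILIVVIFLFFIVIVVLI
LIIVITRDNPHEKLLILILILIFVLIVILLLLLILVDEPHSPADTVRDQHCEAEPHEFLI
VLIFLVVFLLFIVFVLLLILSEQRFKWNQHKESPKN
>SYN-XIP1-2 subfamily=XIP subgroup=XIP1 synthetic=true
---------------------TRGTSHGDHRDSHSRTQTRRNSRKVIIILLVFLILFVIV
IFVVVIFLDRRHDPNQDGSHIIVVFVLVLLFLFVVVFFLFVILPPEGHKSPIKEHTTSST
NSGPG------VFIVILFLILLLVLILILLLVIIGKKPYRRHVILIVVIFIIFIVIVVII
LILVITRDNPEEKLFILILILIFVLIVILFIILILVDEPHSPADTVRDQHCEAEPHGFLI
VLFFLVVFLLFIVFVLLLILSEQRFKWNQHKESPKN
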