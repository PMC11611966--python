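word	ipa
dissuade	dɪswˈeɪd
diswayed	dɪswˈeɪd
dissaude	dɪsˈɔːd
laugh	lˈɑːf
laf	lˈɑːf
bouquet	buːkˈeɪ
bouket	buːkˈeɪ
silhouette	sˌɪluːˈɛt
connoisseur	kˌɒnəsˈɜː
liquorice	lˈɪkəɹɪʃ
bureaucracy	bjʊəɹˈɒkɹəsi
camouflage	kˈaməflɑːʒ
mayonnaise	mˌeɪənˈeɪz
questionnaire	kwˌɛstʃənˈeə
rendezvous	ɹˈɒndeɪvuː
sabotage	sˈabətɑːʒ
moustache	məstˈɑːʃ
aubergine	ˈəʊbəʒiːn
courgette	kʊəʒˈɛt
pharaoh	fˈeəɹəʊ
rhapsody	ɹˈapsədi
pneumonia	njuːmˈəʊniə
diarrhoea	dˌaɪəɹˈiə
haemorrhage	hˈɛməɹɪdʒ
mischievous	mˈɪstʃɪvəs
occurrence	əkˈʌɹəns
embarrass	ɛmbˈaɹəs
millennium	mɪlˈɛniəm
acquiesce	ˌakwiˈɛs
liaison	liˈeɪzɒn
hierarchy	hˈaɪəɹɑːki
vengeance	vˈɛndʒəns
charlatan	ʃˈɑːlətən
picturesque	pˌɪktʃəɹˈɛsk
reservoir	ɹˈɛzəvwɑː
surveillance	səvˈeɪləns
privilege	pɹˈɪvɪlɪdʒ
nauseous	nˈɔːziəs
conscience	kˈɒnʃəns
threshold	θɹˈɛʃəʊld
exhilarate	ɛɡzˈɪləɹeɪt
fluorescent	flʊəɹˈɛsənt
pseudonym	sˈuːdənɪm
subtlety	sˈʌtəlti
leukaemia	luːkˈiːmiə
sovereignty	sˈɒvɹɪnti
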