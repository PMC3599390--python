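species	scientific_name	family	accessions	source	source_detail
Cucumber	Cucumis sativus	TIR-NBS	Cacsa.089350, Cacsa.091460, Cacsa.091470, Cacsa.091680, Cacsa.091690, Cacsa.091710, Cacsa.091780, Cacsa.091820, Cacsa.091840, Cacsa.178450, Cacsa.155730, Cacsa.237390, Cacsa.237410, Cacsa.237440, Cacsa.237520, Cacsa.237530, Cacsa.237540, Cacsa.237560, Cacsa.249360, Cacsa.275630, Cacsa.292710, Cacsa.338650, Cacsa.338660	database	JGI
Cucumber	Cucumis sativus	CC-NBS	Cacsa.017460, Cacsa.017490, Cacsa.088220, Cacsa.091880, Cacsa.094560, Cacsa.094580, Cacsa.094650, Cacsa.094660, Cacsa.094670, Cacsa.102240, Cacsa.123410, Cacsa.128030, Cacsa.128100, Cacsa.128110, Cacsa.128130, Cacsa.128140, Cacsa.132370, Cacsa.133510, Cacsa.163670, Cacsa.178360, Cacsa.178620, Cacsa.189390, Cacsa.237070, Cacsa.239860, Cacsa.248810, Cacsa.251930, Cacsa.277260, Cacsa.318890, Cacsa.326910, Cacsa.328080, Cacsa.337180, Cacsa.37190, Cacsa.338110, Cacsa.338190	database	JGI
Melon	Cucumis melo	TIR-NBS	AF354505, AF354506, AF354510, AF354507, AF354516, AF354511, AF354504, AF354513	reference	B56
Melon	Cucumis melo	CC-NBS	AF354515, AF354509, AF354514, AF354508*, AF354512*	reference	B56
Melon	Cucumis melo	CC-NBS	AY583855	reference	B39
Melon	Cucumis melo	TIR-NBS	JN230661-JN230670	this-study	PCR
Bottle gourd	Lagenaria siceraria	TIR-NBS	JN230598, JN230599, JN230601, JN230602, JN230604, JN230606, JN230607, JN230608, JN230609, JN230612, JN230614, JN230615, JN230618, JN230620-JN230633, JN230635, JN230636, JN230637, JN230638, JN230639	this-study	PCR
Bottle gourd	Lagenaria siceraria	CC-NBS	JN230600, JN230603, JN230605, JN230610, JN230611, JN230613, JN230616, JN230617, JN230619, JN230634, JN230640	this-study	PCR
Luffa	Luffa cylindrica	TIR-NBS	JN230641-JN230660	this-study	PCR
Watermelon	Citrullus lanatus	CC-NBS	DQ156558-DQ156564	database	GenBank
Watermelon	Citrullus lanatus	TIR-NBS	GU124539, GU124541, GU124544, GU124545, GU124546, GU124547, GU124548, GU124550, GU124551, GU124556, GU124557, GU124559, GU124562, GU124563	database	GenBank
Watermelon	Citrullus lanatus	CC-NBS	GU124540, GU124542, GU124543, GU124553#, GU124554#, GU124560*	database	GenBank
Watermelon	Citrullus lanatus	TIR-NBS	JN230671-JN230676, JN230678-JN230701	this-study	PCR
Watermelon	Citrullus lanatus	CC-NBS	JN230677	this-study	PCR
Watermelon	Citrullus colocynthis	TIR-NBS	GU124549, GU124558, GU124561, GU124564	database	GenBank
Watermelon	Citrullus colocynthis	CC-NBS	GU124552*, GU124555*	database	GenBank
Squash	Cucurbita moschata	TIR-NBS	EF199755-EF199758, EF101660-EF101666	database	GenBank
Squash	Cucurbita moschata	CC-NBS	EF199760, EF199759, EF101667	database	GenBank
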