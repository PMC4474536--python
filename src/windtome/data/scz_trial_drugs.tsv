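drug	indication	atc_codes	n_scz_trials
Citalopram	Depression	N06AB04;N06AB10	13
Atomoxetine	ADHD	N06BA09	8
Memantine	Parkinson's disease	N06DX01	6
Paroxetine	Depression	N06AB05	6
Sertraline	Depression	N06AB06	5
Fluvoxamine	Depression	N06AB08	4
Lorazepam	Anxiety	N05BA06	4
Ondansetron	Nausea and vomiting	A04AA01	4
Dexmethylphenidate	ADHD	N06BA11	3
Fluoxetine	Depression	N06AB03	3
Methylphenidate	ADHD	N06BA04	3
Benztropine	Parkinson's disease		2
Betahistine	Obesity	N07CA01	2
Clonidine	ADHD	C02AC01;N02CX02;S01EA04;S01EA03	2
Famotidine	Peptic ulcer disease	A02BA03	2
Guanfacine	Hypertension	C02AC02	2
Mirtazapine	Depression	N06AX11	2
Pergolide	Parkinson's disease	N04BC02	2
Reboxetine	Depression	N06AX18	2
Zolpidem	Insomnia	N05CF02	2
Agomelatine	Depression	N06AX22	1
Bromocriptine	Parkinson's disease	G02CB01;N04BC01	1
Buspirone	Anxiety	N05BE01	1
Cinnarizine	Nausea and vomiting	N07CA02	1
Cyproheptadine	Allergies	R06AX02	1
Desipramine	Depression	N06AA01	1
Dexmedetomidine	Anxiety	N05CM18	1
Diazepam	Anxiety	N05BA01;N05BA17	1
Dopamine	Parkinson's disease	C01CA04	1
Levodopa	Parkinson's disease	N04BA01;N04BA04	1
Methamphetamine	ADHD	N06BA03	1
Naratriptan	Migraine headaches	N02CC02	1
Nitrazepam	Insomnia	N05CD02	1
Nizatidine	Peptic ulcer disease	A02BA04	1
Pramipexole	Parkinson's disease	N04BC05	1
Promethazine	Allergies	D04AA10;R06AD02;R06AD05	1
Sibutramine	Obesity	A08AA10	1
Trazodone	Depression	N06AX05	1
Zotepine		N05AX11	1
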