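rank	name	guild
genus	Methanobacterium	hydrogenotrophic_methanogen
genus	Methanoregula	hydrogenotrophic_methanogen
genus	Methanospirillum	hydrogenotrophic_methanogen
genus	Methanosaeta	aceticlastic_methanogen
genus	Methanosarcina	aceticlastic_methanogen
genus	Ca_Methanoperedens	ANME
genus	ANME-1	ANME
genus	Methylobacter	aerobic_methanotroph
genus	Methylicorpusculum	aerobic_methanotroph
genus	Crenothrix	aerobic_methanotroph
genus	JABFRC01	aerobic_methanotroph
genus	Methylotenera	methylotroph
genus	Methylophilus	methylotroph
genus	Desulfovibrio	sulfate_reducer
genus	Desulfobacca	sulfate_reducer
genus	Desulfosporosinus	sulfate_reducer
genus	Desulfocapsa	sulfate_reducer
genus	Sulfuricurvum	sulfur_oxidizer
genus	Thiobacillus	sulfur_oxidizer
genus	Sulfurimonas	sulfur_oxidizer
genus	Hydrogenophaga	hydrogen_oxidizer
genus	Dechloromonas	dismutation_capable
genus	Nitrospina	dismutation_capable
genus	Nitrobacter	dismutation_capable
genus	Magnetospirillum	dismutation_capable
genus	Sediminibacterium	dismutation_capable
genus	Algoriphagus	dismutation_capable
genus	Nitrosopumilus	dismutation_capable
family	Methylomirabilaceae	dismutation_capable
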