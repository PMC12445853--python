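# leafgx-trait-catalog v1
name	symbol	category	mechanisms	timescale_min	timescale_max	description	units	key_refs
stomatal conductance	g_s	stomata_hydraulics	physiological	minutes	hours	Operational stomatal conductance to water vapour, regulated by guard-cell turgor (aperture)	mol m-2 s-1	review:stomatal-kinetics
internal CO2	c_i	stomata_hydraulics	physiological	seconds	hours	Leaf-internal CO2, set jointly by ambient CO2, stomatal supply and biochemical drawdown	Pa	review:internal-co2
leaf water potential	Psi_leaf	stomata_hydraulics	physiological	minutes	hours	Leaf water status coupled diurnally to transpiration and stomatal regulation	MPa	review:leaf-water-status
leaf hydraulic conductance	K_leaf	stomata_hydraulics	physiological	minutes	months	Hydraulic conductance of the leaf, declining with dehydration from diurnal to seasonal drying	mmol m-2 s-1 MPa-1	review:leaf-hydraulic-conductance
maximum stomatal conductance	g_smax	stomata_hydraulics	phenotypic	years	decades	Anatomical ceiling on stomatal conductance set by stomatal density, pore length and depth of new leaves	mol m-2 s-1	review:stomatal-anatomy
vein length per area	VLA	stomata_hydraulics	phenotypic|evolutionary	years	centuries	Vein density; enables higher hydraulic and stomatal conductance per leaf area, less plastic than stomatal density	mm mm-2	review:vein-architecture
hydraulic capacity	K_leaf_max	stomata_hydraulics	evolutionary	decades	centuries	Maximum leaf hydraulic conductance set by vein architecture, xylem and mesophyll anatomy	mmol m-2 s-1 MPa-1	review:hydraulic-capacity-evolution
optimal ci:ca ratio	chi_optimal	stomata_hydraulics|photosynthetic_biochemistry	phenotypic	weeks	months	Least-cost optimal time-averaged ratio of internal to ambient CO2, acclimating with carboxylation capacity	-	review:chi-acclimation
maximum carboxylation rate	V_cmax	photosynthetic_biochemistry	phenotypic	weeks	weeks	Maximum Rubisco carboxylation rate, downregulated under elevated CO2 and retuned to growth temperature	umol m-2 s-1	review:capacity-acclimation
maximum electron transport rate	J_max	photosynthetic_biochemistry	phenotypic	weeks	weeks	Maximum electron transport rate, co-acclimating with V_cmax at a declining ratio under warming and elevated CO2	umol m-2 s-1	review:capacity-acclimation
light-saturated photosynthetic capacity	A_sat	photosynthetic_biochemistry	evolutionary	decades	centuries	Maximum light-saturated assimilation, coordinated with hydraulic capacity across lineages	umol m-2 s-1	review:photosynthesis-hydraulics-coordination
photosynthetic pathway		photosynthetic_biochemistry	evolutionary	centuries	millions_of_years	C3, C4 or CAM carbon fixation strategy, requiring coupled anatomical and biochemical change	-	review:photosynthetic-pathway-evolution
leaf mass per area	LMA	morphology_lifespan	phenotypic|evolutionary	years	centuries	Leaf dry mass per area (LMA = LD x LVA), tracking light, CO2 and temperature at leaf development	g m-2	review:leaf-economics
leaf density	LD	morphology_lifespan	phenotypic|evolutionary	years	centuries	Leaf tissue density component of LMA, increased by low temperature via limited cell expansion	g cm-3	review:leaf-economics
leaf volume per area	LVA	morphology_lifespan	phenotypic|evolutionary	years	centuries	Leaf thickness component of LMA, increased under high light via extra mesophyll layers	cm3 m-2	review:leaf-economics
leaf lifespan	LL	morphology_lifespan	phenotypic|evolutionary	years	centuries	Timespan of carbon return on leaf construction costs; longer in shade and in conservative strategies	months	review:leaf-economics
genome size		morphology_lifespan	evolutionary	millions_of_years	millions_of_years	Genome size constrains minimum cell size and thereby stomatal, vein and mesophyll trait coordination	Gb	review:genome-size
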