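# Human red blood cell metabolic network (39 metabolites, 51 reactions).
# Reconstruction of the classic erythrocyte stoichiometric model covering
# glycolysis, the Rapoport-Luebering shunt, the pentose phosphate pathway and
# adenosine nucleotide salvage, with cofactor loads expressed as exchange
# fluxes.  Exchange reactions are written one-sided; "<->" marks reversible.
#
# glycolysis
HK: GLC + ATP -> G6P + ADP + H
PGI: G6P <-> F6P
PFK: F6P + ATP -> FDP + ADP + H
ALD: FDP <-> DHAP + GA3P
TPI: DHAP <-> GA3P
GAPDH: GA3P + NAD + Pi <-> DPG13 + NADH + H
PGK: DPG13 + ADP <-> PG3 + ATP
PGM: PG3 <-> PG2
EN: PG2 <-> PEP + H2O
PK: PEP + ADP + H -> PYR + ATP
LDH: PYR + NADH + H <-> LAC + NAD
# Rapoport-Luebering shunt
DPGM: DPG13 -> DPG23
DPGase: DPG23 + H2O -> PG3 + Pi
# pentose phosphate pathway, oxidative branch
G6PDH: G6P + NADP -> GL6P + NADPH + H
PGL: GL6P + H2O -> GO6P + H
PDGH: GO6P + NADP -> RU5P + NADPH + CO2
# pentose phosphate pathway, non-oxidative branch
R5PI: RU5P <-> R5P
Xu5PE: RU5P <-> X5P
TKI: X5P + R5P <-> GA3P + S7P
TA: GA3P + S7P <-> E4P + F6P
TKII: X5P + E4P <-> F6P + GA3P
# adenosine nucleotide metabolism
PRPPsyn: R5P + ATP -> PRPP + AMP + H
PRM: R1P <-> R5P
HGPRT: HX + PRPP -> IMP
AdPRT: ADE + PRPP -> AMP
AMPase: AMP + H2O -> ADO + Pi
ADA: ADO + H2O -> INO + NH3
AK: ADO + ATP -> AMP + ADP + H
ApK: 2 ADP <-> ATP + AMP
AMPDA: AMP + H2O -> IMP + NH3
IMPase: IMP + H2O -> INO + Pi
PNPase: INO + Pi <-> HX + R1P
# primary exchange fluxes
EX_GLC: -> GLC
EX_PYR: PYR ->
EX_LAC: LAC ->
EX_CO2: CO2 ->
EX_NH3: NH3 ->
EX_ADE: -> ADE
EX_ADO: ADO <->
EX_INO: INO <->
EX_HX: -> HX
EX_DPG23: DPG23 ->
# cofactor loads / currency exchange fluxes
EX_Pi: Pi <->
EX_ATP: ATP <->
EX_ADP: ADP <->
EX_NAD: NAD <->
EX_NADH: NADH <->
EX_NADP: NADP <->
EX_NADPH: NADPH <->
EX_H2O: H2O <->
EX_H: H <->
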