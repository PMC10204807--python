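"""Curated reaction table of the core C3-leaf carbon metabolism model.

A mesophyll-cell network spanning cytosol (c), chloroplast (h), mitochondrion
(m) and peroxisome (x), plus an external compartment (e).  The table is the
single source of truth for :func:`leafcbm.fixtures.build_fixture_leaf_model`;
biomass stoichiometry is the only part computed from configuration.

Conventions
-----------
* Equations use the TSV-dialect syntax (``->`` irreversible, ``<->``
  reversible, coefficients prefix the species id).
* Formulas track C, N, P and S exactly; hydrogen/oxygen bookkeeping is
  approximate because protons and some waters are omitted from lumped steps
  (light reactions, electron transport, assimilatory reductions).
* Several canonical multi-step segments are lumped into single reactions
  (Calvin regeneration, non-oxidative pentose phosphate, plastid fatty-acid
  synthesis including its pyruvate-dehydrogenase redox credit, sulfate
  assimilation, the two mitochondrial electron-transport entry points).
* Antiporter shuttles are written as single two-substrate reactions so the
  shuttle flux is a well-defined single number (malate/OAA valve between
  chloroplast and cytosol, mitochondrial and peroxisomal malate/OAA
  shuttles, mitochondrial ATP/ADP translocator).
* Photons are massless (no formula); light reactions are therefore exempt
  from the elemental balance check by construction.
"""

from __future__ import annotations

COMPARTMENTS = {
    "c": "cytosol",
    "h": "chloroplast",
    "m": "mitochondrion",
    "x": "peroxisome",
    "e": "external",
}

# (id, name, compartment, formula, role)
METABOLITES = [
    # external pool
    ("co2_e", "CO2", "e", "CO2", "co2_external"),
    ("o2_e", "O2", "e", "O2", None),
    ("h2o_e", "water", "e", "H2O", None),
    ("pi_e", "orthophosphate", "e", "HO4P", None),
    ("no3_e", "nitrate", "e", "NO3", None),
    ("so4_e", "sulfate", "e", "O4S", None),
    ("nh3_e", "ammonia", "e", "H3N", None),
    ("photon_e", "photon", "e", None, None),
    ("sucr_e", "sucrose (exported)", "e", "C12H22O11", None),
    # cytosol
    ("co2_c", "CO2", "c", "CO2", "co2"),
    ("hco3_c", "bicarbonate", "c", "CHO3", "bicarbonate"),
    ("o2_c", "O2", "c", "O2", None),
    ("h2o_c", "water", "c", "H2O", None),
    ("pi_c", "orthophosphate", "c", "HO4P", None),
    ("no3_c", "nitrate", "c", "NO3", None),
    ("no2_c", "nitrite", "c", "NO2", None),
    ("nh4_c", "ammonium", "c", "H3N", None),
    ("so4_c", "sulfate", "c", "O4S", None),
    ("h2s_c", "sulfide", "c", "H2S", None),
    ("atp_c", "ATP", "c", "C10H16N5O13P3", "atp"),
    ("adp_c", "ADP", "c", "C10H15N5O10P2", None),
    ("nad_c", "NAD+", "c", "C21H27N7O14P2", None),
    ("nadh_c", "NADH", "c", "C21H28N7O14P2", "nadh"),
    ("nadp_c", "NADP+", "c", "C21H28N7O17P3", None),
    ("nadph_c", "NADPH", "c", "C21H29N7O17P3", "nadph"),
    ("utp_c", "UTP", "c", "C9H15N2O15P3", None),
    ("udp_c", "UDP", "c", "C9H14N2O12P2", None),
    ("ppi_c", "pyrophosphate", "c", "H4O7P2", None),
    ("gap_c", "glyceraldehyde 3-phosphate", "c", "C3H7O6P", None),
    ("dhap_c", "dihydroxyacetone phosphate", "c", "C3H7O6P", None),
    ("fbp_c", "fructose 1,6-bisphosphate", "c", "C6H14O12P2", None),
    ("f6p_c", "fructose 6-phosphate", "c", "C6H13O9P", None),
    ("g6p_c", "glucose 6-phosphate", "c", "C6H13O9P", None),
    ("g1p_c", "glucose 1-phosphate", "c", "C6H13O9P", None),
    ("udpg_c", "UDP-glucose", "c", "C15H24N2O17P2", None),
    ("pg6_c", "6-phosphogluconate", "c", "C6H13O10P", None),
    ("ru5p_c", "ribulose 5-phosphate", "c", "C5H11O8P", None),
    ("s6p_c", "sucrose 6-phosphate", "c", "C12H23O14P", None),
    ("suc_c", "sucrose", "c", "C12H22O11", None),
    ("pga_c", "3-phosphoglycerate", "c", "C3H7O7P", None),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H5O6P", None),
    ("pyr_c", "pyruvate", "c", "C3H4O3", None),
    ("oaa_c", "oxaloacetate", "c", "C4H4O5", None),
    ("mal_c", "malate", "c", "C4H6O5", None),
    ("akg_c", "2-oxoglutarate", "c", "C5H6O5", None),
    ("glu_c", "glutamate", "c", "C5H9NO4", None),
    ("gln_c", "glutamine", "c", "C5H10N2O3", None),
    ("asp_c", "aspartate", "c", "C4H7NO4", None),
    ("ala_c", "alanine", "c", "C3H7NO2", None),
    ("ser_c", "serine", "c", "C3H7NO3", None),
    ("gly_c", "glycine", "c", "C2H5NO2", None),
    ("cys_c", "cysteine", "c", "C3H7NO2S", None),
    ("glyc_c", "glycolate", "c", "C2H4O3", None),
    ("glycerate_c", "glycerate", "c", "C3H6O4", None),
    ("palm_c", "palmitate", "c", "C16H32O2", None),
    ("carbpool_c", "carbohydrate pool (hexose units)", "c", "C6H12O6", None),
    ("protpool_c", "protein pool (mean residue)", "c",
     "C3.56H5.34N1.1O1.92S0.06", None),
    ("cellulose_c", "cellulose (glucan units)", "c", "C6H10O5", None),
    # chloroplast
    ("photon_h", "photon", "h", None, None),
    ("co2_h", "CO2", "h", "CO2", "co2"),
    ("o2_h", "O2", "h", "O2", None),
    ("h2o_h", "water", "h", "H2O", None),
    ("pi_h", "orthophosphate", "h", "HO4P", None),
    ("atp_h", "ATP", "h", "C10H16N5O13P3", "atp"),
    ("adp_h", "ADP", "h", "C10H15N5O10P2", None),
    ("amp_h", "AMP", "h", "C10H14N5O7P", None),
    ("ppi_h", "pyrophosphate", "h", "H4O7P2", None),
    ("nadp_h", "NADP+", "h", "C21H28N7O17P3", None),
    ("nadph_h", "NADPH", "h", "C21H29N7O17P3", "nadph"),
    ("rubp_h", "ribulose 1,5-bisphosphate", "h", "C5H12O11P2", None),
    ("pga_h", "3-phosphoglycerate", "h", "C3H7O7P", None),
    ("gap_h", "glyceraldehyde 3-phosphate", "h", "C3H7O6P", None),
    ("dhap_h", "dihydroxyacetone phosphate", "h", "C3H7O6P", None),
    ("fbp_h", "fructose 1,6-bisphosphate", "h", "C6H14O12P2", None),
    ("f6p_h", "fructose 6-phosphate", "h", "C6H13O9P", None),
    ("g6p_h", "glucose 6-phosphate", "h", "C6H13O9P", None),
    ("g1p_h", "glucose 1-phosphate", "h", "C6H13O9P", None),
    ("adpg_h", "ADP-glucose", "h", "C16H25N5O15P2", None),
    ("starch_h", "starch (glucan units)", "h", "C6H10O5", None),
    ("ru5p_h", "ribulose 5-phosphate", "h", "C5H11O8P", None),
    ("pglyc_h", "2-phosphoglycolate", "h", "C2H5O6P", None),
    ("glyc_h", "glycolate", "h", "C2H4O3", None),
    ("glycerate_h", "glycerate", "h", "C3H6O4", None),
    ("mal_h", "malate", "h", "C4H6O5", None),
    ("oaa_h", "oxaloacetate", "h", "C4H4O5", None),
    ("pyr_h", "pyruvate", "h", "C3H4O3", None),
    ("pep_h", "phosphoenolpyruvate", "h", "C3H5O6P", None),
    ("akg_h", "2-oxoglutarate", "h", "C5H6O5", None),
    ("glu_h", "glutamate", "h", "C5H9NO4", None),
    ("gln_h", "glutamine", "h", "C5H10N2O3", None),
    ("nh4_h", "ammonium", "h", "H3N", None),
    ("no2_h", "nitrite", "h", "NO2", None),
    ("palm_h", "palmitate", "h", "C16H32O2", None),
    # mitochondrion
    ("co2_m", "CO2", "m", "CO2", "co2"),
    ("o2_m", "O2", "m", "O2", None),
    ("h2o_m", "water", "m", "H2O", None),
    ("pi_m", "orthophosphate", "m", "HO4P", None),
    ("atp_m", "ATP", "m", "C10H16N5O13P3", "atp"),
    ("adp_m", "ADP", "m", "C10H15N5O10P2", None),
    ("nad_m", "NAD+", "m", "C21H27N7O14P2", None),
    ("nadh_m", "NADH", "m", "C21H28N7O14P2", "nadh"),
    ("q_m", "ubiquinone", "m", "C49H74O4", None),
    ("qh2_m", "ubiquinol", "m", "C49H76O4", None),
    ("coa_m", "coenzyme A", "m", "C21H36N7O16P3S", None),
    ("accoa_m", "acetyl-CoA", "m", "C23H38N7O17P3S", None),
    ("pyr_m", "pyruvate", "m", "C3H4O3", None),
    ("cit_m", "citrate", "m", "C6H8O7", None),
    ("akg_m", "2-oxoglutarate", "m", "C5H6O5", None),
    ("succ_m", "succinate", "m", "C4H6O4", None),
    ("fum_m", "fumarate", "m", "C4H4O4", None),
    ("mal_m", "malate", "m", "C4H6O5", None),
    ("oaa_m", "oxaloacetate", "m", "C4H4O5", None),
    ("gly_m", "glycine", "m", "C2H5NO2", None),
    ("ser_m", "serine", "m", "C3H7NO3", None),
    ("nh4_m", "ammonium", "m", "H3N", None),
    # peroxisome
    ("o2_x", "O2", "x", "O2", None),
    ("h2o_x", "water", "x", "H2O", None),
    ("h2o2_x", "hydrogen peroxide", "x", "H2O2", None),
    ("glyc_x", "glycolate", "x", "C2H4O3", None),
    ("glx_x", "glyoxylate", "x", "C2H2O3", None),
    ("gly_x", "glycine", "x", "C2H5NO2", None),
    ("ser_x", "serine", "x", "C3H7NO3", None),
    ("hpyr_x", "hydroxypyruvate", "x", "C3H4O4", None),
    ("glycerate_x", "glycerate", "x", "C3H6O4", None),
    ("glu_x", "glutamate", "x", "C5H9NO4", None),
    ("akg_x", "2-oxoglutarate", "x", "C5H6O5", None),
    ("mal_x", "malate", "x", "C4H6O5", None),
    ("oaa_x", "oxaloacetate", "x", "C4H4O5", None),
    ("nad_x", "NAD+", "x", "C21H27N7O14P2", None),
    ("nadh_x", "NADH", "x", "C21H28N7O14P2", "nadh"),
]

# (id, name, equation, lb, ub, gpr, pathway, ec, role)
# lb None -> 0 for "->", -1000 for "<->"; ub None -> 1000.
REACTIONS = [
    # ------------------------------------------------------------ exchanges
    ("EX_co2", "CO2 exchange", "co2_e ->", None, None, "", "exchange", "",
     "co2_exchange"),
    ("EX_o2", "O2 exchange", "o2_e <->", None, None, "", "exchange", "", None),
    ("EX_h2o", "water exchange", "h2o_e <->", None, None, "", "exchange", "", None),
    ("EX_pi", "phosphate exchange", "pi_e <->", None, None, "", "exchange", "", None),
    ("EX_no3", "nitrate exchange", "no3_e <->", None, None, "", "exchange", "", None),
    ("EX_so4", "sulfate exchange", "so4_e <->", None, None, "", "exchange", "", None),
    ("EX_photon", "photon uptake", "photon_e ->", None, 0.0, "", "exchange", "",
     "photon_exchange"),
    ("EX_sucr", "sucrose export", "sucr_e ->", 0.0, None, "", "exchange", "",
     "sucrose_exchange"),
    ("EX_nh3", "ammonia exchange (closed: photorespiratory NH3 is refixed)",
     "nh3_e ->", 0.0, 0.0, "", "exchange", "", None),
    # ------------------------------------------------- envelope transports
    ("T_co2_ec", "CO2 stomatal diffusion", "co2_e <-> co2_c", None, None, "",
     "transport", "", "co2_stomatal"),
    ("T_o2_ec", "O2 diffusion", "o2_e <-> o2_c", None, None, "", "transport", "", None),
    ("T_h2o_ec", "water flux", "h2o_e <-> h2o_c", None, None, "", "transport", "", None),
    ("T_pi_ec", "phosphate uptake", "pi_e <-> pi_c", None, None, "", "transport", "", None),
    ("T_no3_ec", "nitrate uptake", "no3_e -> no3_c", None, None, "", "transport", "", None),
    ("T_so4_ec", "sulfate uptake", "so4_e -> so4_c", None, None, "", "transport", "", None),
    ("T_photon_eh", "light absorption", "photon_e -> photon_h", None, None, "",
     "transport", "", None),
    ("T_sucr_ce", "sucrose phloem loading", "suc_c -> sucr_e", None, None, "",
     "transport", "", "sucrose_export"),
    ("T_nh3_ce", "ammonia efflux", "nh4_c -> nh3_e", None, None, "", "transport", "", None),
    # ----------------------------------------------- intracellular diffusion
    ("T_co2_ch", "CO2 diffusion into stroma", "co2_c <-> co2_h", None, None, "",
     "transport", "", "chloroplast_co2_import"),
    ("T_co2_mc", "CO2 diffusion out of mitochondrion", "co2_m <-> co2_c",
     None, None, "", "transport", "", None),
    ("T_o2_hc", "O2 diffusion", "o2_h <-> o2_c", None, None, "", "transport", "", None),
    ("T_o2_cm", "O2 diffusion", "o2_c <-> o2_m", None, None, "", "transport", "", None),
    ("T_o2_cx", "O2 diffusion", "o2_c <-> o2_x", None, None, "", "transport", "", None),
    ("T_h2o_ch", "water flux", "h2o_c <-> h2o_h", None, None, "", "transport", "", None),
    ("T_h2o_cm", "water flux", "h2o_c <-> h2o_m", None, None, "", "transport", "", None),
    ("T_h2o_cx", "water flux", "h2o_c <-> h2o_x", None, None, "", "transport", "", None),
    ("T_pi_ch", "phosphate translocator", "pi_c <-> pi_h", None, None, "",
     "transport", "", None),
    ("T_pi_cm", "phosphate carrier", "pi_c <-> pi_m", None, None, "",
     "transport", "", None),
    # ------------------------------------------------------ light reactions
    ("LEF_h", "linear electron flow (PSII+PSI+ATP synthase)",
     "8 photon_h + 2 h2o_h + 2 nadp_h + 2.6 adp_h + 2.6 pi_h -> "
     "o2_h + 2 nadph_h + 2.6 atp_h",
     None, None, "g_psbA and g_psaA and g_atpB", "light_reactions", "", None),
    ("CEF_h", "cyclic electron flow (PSI+ATP synthase)",
     "2 photon_h + adp_h + pi_h -> atp_h",
     None, None, "g_pgr5 and g_atpB", "light_reactions", "", None),
    # --------------------------------------------------------- Calvin cycle
    ("RBC_carb", "RuBisCO carboxylase",
     "rubp_h + co2_h + h2o_h -> 2 pga_h", None, None,
     "g_rbcL and g_rbcS1", "calvin_cycle", "4.1.1.39", "rubisco_carboxylase"),
    ("RBC_oxy", "RuBisCO oxygenase",
     "rubp_h + o2_h -> pga_h + pglyc_h", None, None,
     "g_rbcL and g_rbcS1", "calvin_cycle", "4.1.1.39", "rubisco_oxygenase"),
    ("PGA_red_h", "PGA reduction (PGK + NADP-GAPDH)",
     "pga_h + atp_h + nadph_h -> gap_h + adp_h + pi_h + nadp_h",
     None, None, "g_pgk1 and g_gapA", "calvin_cycle", "", None),
    ("TPI_h", "triose-phosphate isomerase", "gap_h <-> dhap_h",
     None, None, "g_tpiP", "calvin_cycle", "5.3.1.1", None),
    ("ALD_h", "FBP aldolase", "gap_h + dhap_h <-> fbp_h",
     None, None, "g_fbaP", "calvin_cycle", "4.1.2.13", None),
    ("FBPase_h", "plastid FBPase", "fbp_h + h2o_h -> f6p_h + pi_h",
     None, None, "g_fbp1", "calvin_cycle", "3.1.3.11", None),
    ("REGEN_h", "RuBP regeneration segment (TK/TA/RPE/RPI, lumped)",
     "2 f6p_h + gap_h -> 3 ru5p_h", None, None, "g_tktP", "calvin_cycle", "", None),
    ("PRK_h", "phosphoribulokinase", "ru5p_h + atp_h -> rubp_h + adp_h",
     None, None, "g_prk1", "calvin_cycle", "2.7.1.19", None),
    # --------------------------------------------------- starch and sucrose
    ("PGI_h", "plastid PGI", "f6p_h <-> g6p_h", None, None, "g_pgiP",
     "starch_sucrose", "5.3.1.9", None),
    ("PGM_h", "plastid phosphoglucomutase", "g6p_h <-> g1p_h", None, None,
     "g_pgmP", "starch_sucrose", "5.4.2.2", None),
    ("AGPase_h", "ADP-glucose pyrophosphorylase",
     "g1p_h + atp_h -> adpg_h + ppi_h", None, None, "g_agp1", "starch_sucrose",
     "2.7.7.27", None),
    ("SS_h", "starch synthase", "adpg_h -> starch_h + adp_h", None, None,
     "g_ss1", "starch_sucrose", "2.4.1.21", None),
    ("SP_h", "starch phosphorylase", "starch_h + pi_h -> g1p_h", None, None,
     "g_pho1", "starch_sucrose", "2.4.1.1", None),
    ("PPIase_h", "plastid inorganic pyrophosphatase",
     "ppi_h + h2o_h -> 2 pi_h", None, None, "", "starch_sucrose", "3.6.1.1", None),
    ("TPI_c", "cytosolic TPI", "gap_c <-> dhap_c", None, None, "g_tpiC",
     "starch_sucrose", "5.3.1.1", None),
    ("ALD_c", "cytosolic aldolase", "gap_c + dhap_c <-> fbp_c", None, None,
     "g_fbaC", "starch_sucrose", "4.1.2.13", None),
    ("FBPase_c", "cytosolic FBPase", "fbp_c + h2o_c -> f6p_c + pi_c",
     None, None, "g_fbp2", "starch_sucrose", "3.1.3.11", None),
    ("PGI_c", "cytosolic PGI", "f6p_c <-> g6p_c", None, None, "g_pgiC",
     "starch_sucrose", "5.3.1.9", None),
    ("PGM_c", "cytosolic phosphoglucomutase", "g6p_c <-> g1p_c", None, None,
     "g_pgmC", "starch_sucrose", "5.4.2.2", None),
    ("UGPase_c", "UDP-glucose pyrophosphorylase",
     "g1p_c + utp_c -> udpg_c + ppi_c", None, None, "g_ugp1", "starch_sucrose",
     "2.7.7.9", None),
    ("NDPK_c", "nucleoside-diphosphate kinase", "udp_c + atp_c <-> utp_c + adp_c",
     None, None, "", "starch_sucrose", "2.7.4.6", None),
    ("PPIase_c", "cytosolic inorganic pyrophosphatase",
     "ppi_c + h2o_c -> 2 pi_c", None, None, "", "starch_sucrose", "3.6.1.1", None),
    ("SPS_c", "sucrose-phosphate synthase",
     "udpg_c + f6p_c -> s6p_c + udp_c", None, None, "g_sps1 or g_sps2",
     "starch_sucrose", "2.4.1.14", "sps"),
    ("SPP_c", "sucrose-phosphate phosphatase",
     "s6p_c + h2o_c -> suc_c + pi_c", None, None, "g_spp1 or g_spp2",
     "starch_sucrose", "3.1.3.24", "spp"),
    ("CARB_c", "carbohydrate pool formation (hexose units from sucrose)",
     "suc_c + h2o_c -> 2 carbpool_c", None, None, "", "starch_sucrose", "", None),
    # ------------------------------------------------------------ cell wall
    ("CESA_c", "cellulose synthase", "udpg_c -> cellulose_c + udp_c",
     None, None, "g_cesa1 or g_cesa2", "cell_wall", "2.4.1.12", None),
    # ------------------------------------------------------ photorespiration
    ("PGP_h", "phosphoglycolate phosphatase",
     "pglyc_h + h2o_h -> glyc_h + pi_h", None, None, "g_pgp1",
     "photorespiration", "3.1.3.18", None),
    ("T_glyc_hc", "glycolate export from chloroplast", "glyc_h -> glyc_c",
     None, None, "", "transport", "", None),
    ("T_glyc_cx", "glycolate import into peroxisome", "glyc_c -> glyc_x",
     None, None, "", "transport", "", None),
    ("GOX_x", "glycolate oxidase", "glyc_x + o2_x -> glx_x + h2o2_x",
     None, None, "g_gox1", "photorespiration", "1.1.3.15", None),
    ("CAT_x", "catalase", "h2o2_x -> h2o_x + 0.5 o2_x", None, None, "g_cat1",
     "photorespiration", "1.11.1.6", None),
    ("GGAT_x", "glutamate:glyoxylate aminotransferase",
     "glx_x + glu_x -> gly_x + akg_x", None, None, "g_ggat1",
     "photorespiration", "2.6.1.4", None),
    ("SGAT_x", "serine:glyoxylate aminotransferase",
     "glx_x + ser_x -> gly_x + hpyr_x", None, None, "g_sgat1",
     "photorespiration", "2.6.1.45", None),
    ("HPR_x", "hydroxypyruvate reductase",
     "hpyr_x + nadh_x -> glycerate_x + nad_x", None, None, "g_hpr1",
     "photorespiration", "1.1.1.29", None),
    ("GDC_m", "glycine decarboxylase + SHMT (lumped)",
     "2 gly_m + nad_m + h2o_m -> ser_m + co2_m + nh4_m + nadh_m",
     None, None, "g_gldP1 and g_gldT and g_shm1", "photorespiration",
     "1.4.4.2", "gdc"),
    ("GLYK_h", "glycerate kinase", "glycerate_h + atp_h -> pga_h + adp_h",
     None, None, "g_glyk1", "photorespiration", "2.7.1.31", None),
    ("T_gly_xm", "glycine shuttle to mitochondrion", "gly_x -> gly_m",
     None, None, "", "transport", "", None),
    ("T_gly_xc", "glycine export to cytosol", "gly_x -> gly_c",
     None, None, "", "transport", "", None),
    ("T_ser_mx", "serine return to peroxisome", "ser_m -> ser_x",
     None, None, "", "transport", "", None),
    ("T_ser_mc", "serine export to cytosol", "ser_m -> ser_c",
     None, None, "", "transport", "", None),
    ("T_glycerate_xc", "glycerate export", "glycerate_x -> glycerate_c",
     None, None, "", "transport", "", None),
    ("T_glycerate_ch", "glycerate import into chloroplast",
     "glycerate_c -> glycerate_h", None, None, "", "transport", "", None),
    ("T_nh4_mc", "photorespiratory ammonium release", "nh4_m -> nh4_c",
     None, None, "", "transport", "", None),
    # ------------------------------------------------------------- C4 cycle
    ("CA_c", "carbonic anhydrase", "co2_c + h2o_c <-> hco3_c", None, None,
     "g_ca1 or g_ca2", "c4_cycle", "4.2.1.1", "carbonic_anhydrase"),
    ("PEPC_c", "phosphoenolpyruvate carboxylase",
     "pep_c + hco3_c -> oaa_c + pi_c", None, None,
     "g_pepc1 or g_pepc2 or g_pepc3", "c4_cycle", "4.1.1.31", "pepc"),
    ("PEPCK_c", "phosphoenolpyruvate carboxykinase",
     "oaa_c + atp_c -> pep_c + co2_c + adp_c", None, None,
     "g_pepck1 or g_pepck2", "c4_cycle", "4.1.1.49", "pepck"),
    ("NADPME_h", "NADP-malic enzyme (chloroplast)",
     "mal_h + nadp_h -> pyr_h + co2_h + nadph_h", None, None, "g_me1",
     "c4_cycle", "1.1.1.40", "nadp_me"),
    ("NADME_m", "NAD-malic enzyme (mitochondrion)",
     "mal_m + nad_m -> pyr_m + co2_m + nadh_m", None, None, "g_me2",
     "c4_cycle", "1.1.1.39", "nad_me"),
    ("PPDK_h", "pyruvate,orthophosphate dikinase",
     "pyr_h + atp_h + pi_h -> pep_h + amp_h + ppi_h", None, None, "g_ppdk1",
     "c4_cycle", "2.7.9.1", None),
    ("ADK_h", "adenylate kinase", "amp_h + atp_h <-> 2 adp_h", None, None,
     "", "c4_cycle", "2.7.4.3", None),
    # ---------------------------------------------------------- respiration
    ("GAPDH_PGK_c", "cytosolic gluconeogenic GAPDH + PGK (lumped; the "
     "glycolytic direction is off in the lit leaf, which exports PGA/triose "
     "from the chloroplast instead)",
     "pga_c + atp_c + nadh_c -> gap_c + adp_c + pi_c + nad_c", None, None,
     "g_gapC and g_pgk2", "respiration", "", None),
    ("ENO_c", "phosphoglycerate mutase + enolase (lumped)",
     "pga_c <-> pep_c + h2o_c", None, None, "g_eno1", "respiration",
     "4.2.1.11", None),
    ("PK_c", "pyruvate kinase", "pep_c + adp_c -> pyr_c + atp_c", None, None,
     "g_pk1", "respiration", "2.7.1.40", None),
    ("MDH_c", "cytosolic NAD-malate dehydrogenase",
     "oaa_c + nadh_c <-> mal_c + nad_c", None, None, "g_mdh1 or g_mdh2",
     "respiration", "1.1.1.37", "mdh_nad_c"),
    ("MDH_NADP_h", "chloroplast NADP-malate dehydrogenase (malate valve)",
     "oaa_h + nadph_h <-> mal_h + nadp_h", None, None, "g_mdh5 or g_mdh6",
     "respiration", "1.1.1.82", "mdh_nadp_h"),
    ("MDH_x", "peroxisomal NAD-malate dehydrogenase",
     "mal_x + nad_x <-> oaa_x + nadh_x", None, None, "g_mdh3", "respiration",
     "1.1.1.37", None),
    ("T_pyr_cm", "pyruvate carrier", "pyr_c <-> pyr_m", None, None, "",
     "transport", "", None),
    ("T_oaa_cm", "mitochondrial oxaloacetate carrier", "oaa_c <-> oaa_m",
     None, None, "", "transport", "", None),
    ("PDH_m", "pyruvate dehydrogenase complex",
     "pyr_m + coa_m + nad_m -> accoa_m + co2_m + nadh_m", None, None,
     "g_pdh1", "respiration", "1.2.4.1", None),
    ("CS_m", "citrate synthase", "accoa_m + oaa_m + h2o_m -> cit_m + coa_m",
     None, None, "g_cs1", "respiration", "2.3.3.1", None),
    ("IDH_m", "aconitase + NAD-isocitrate dehydrogenase (lumped)",
     "cit_m + nad_m -> akg_m + co2_m + nadh_m", None, None, "g_idh1",
     "respiration", "1.1.1.41", None),
    ("OGDH_m", "2-oxoglutarate dehydrogenase + succinyl-CoA synthetase (lumped)",
     "akg_m + nad_m + adp_m + pi_m -> succ_m + co2_m + nadh_m + atp_m",
     None, None, "g_ogdh1", "respiration", "1.2.4.2", None),
    ("SDH_m", "succinate dehydrogenase", "succ_m + q_m -> fum_m + qh2_m",
     None, None, "g_sdh1", "respiration", "1.3.5.1", None),
    ("FUM_m", "fumarase", "fum_m + h2o_m -> mal_m", None, None, "g_fum1",
     "respiration", "4.2.1.2", None),
    ("MDH_m", "mitochondrial NAD-malate dehydrogenase",
     "mal_m + nad_m <-> oaa_m + nadh_m", None, None, "g_mdh4", "respiration",
     "1.1.1.37", "mdh_nad_m"),
    ("ETC1_m", "complex I-proximal electron transport (NADH to O2, lumped)",
     "nadh_m + 0.5 o2_m + 2.5 adp_m + 2.5 pi_m -> nad_m + 2.5 atp_m + h2o_m",
     None, None, "g_cox1 and g_atp1", "respiration", "", None),
    ("ETC2_m", "ubiquinol-proximal electron transport (lumped)",
     "qh2_m + 0.5 o2_m + 1.5 adp_m + 1.5 pi_m -> q_m + 1.5 atp_m + h2o_m",
     None, None, "g_cox1 and g_atp1", "respiration", "", None),
    # ------------------------------------------------------------- shuttles
    ("T_dct_hc", "chloroplast malate/OAA shuttle (antiport)",
     "mal_h + oaa_c <-> mal_c + oaa_h", None, None, "", "transport", "",
     "nadh_shuttle_hc"),
    ("T_mal_oaa_cm", "mitochondrial malate/OAA shuttle (antiport)",
     "mal_c + oaa_m <-> mal_m + oaa_c", None, None, "", "transport", "",
     "nadh_shuttle_cm"),
    ("T_mal_oaa_cx", "peroxisomal malate/OAA shuttle (antiport)",
     "mal_c + oaa_x <-> mal_x + oaa_c", None, None, "", "transport", "",
     "nadh_shuttle_cx"),
    ("T_atp_adp_mc", "mitochondrial ATP/ADP translocator (antiport, "
     "export-only in the respiring direction)",
     "atp_m + adp_c -> atp_c + adp_m", None, None, "", "transport", "",
     "atp_shuttle_mc"),
    ("T_mal_ch", "chloroplast malate carrier (net dicarboxylate transport)",
     "mal_c <-> mal_h", None, None, "", "transport", "", None),
    ("T_mal_cm", "mitochondrial dicarboxylate carrier (net malate import)",
     "mal_c <-> mal_m", None, None, "", "transport", "", None),
    ("T_gap_hc", "triose-phosphate translocator", "gap_h <-> gap_c",
     None, None, "", "transport", "", None),
    ("T_pga_ch", "PGA translocator", "pga_c <-> pga_h", None, None, "",
     "transport", "", None),
    ("T_pep_hc", "PEP translocator", "pep_h <-> pep_c", None, None, "",
     "transport", "", None),
    ("T_pyr_ch", "pyruvate transport", "pyr_c <-> pyr_h", None, None, "",
     "transport", "", None),
    ("T_akg_ch", "2-oxoglutarate translocator", "akg_c <-> akg_h", None, None,
     "", "transport", "", None),
    ("T_akg_mc", "2-oxoglutarate export (anaplerotic)", "akg_m -> akg_c",
     None, None, "", "transport", "", None),
    ("T_glu_hc", "glutamate translocator", "glu_h <-> glu_c", None, None, "",
     "transport", "", None),
    ("T_gln_ch", "glutamine translocator", "gln_c <-> gln_h", None, None, "",
     "transport", "", None),
    ("T_glu_cx", "glutamate import into peroxisome", "glu_c -> glu_x",
     None, None, "", "transport", "", None),
    ("T_akg_xc", "2-oxoglutarate return from peroxisome", "akg_x -> akg_c",
     None, None, "", "transport", "", None),
    ("T_no2_ch", "nitrite import into chloroplast", "no2_c -> no2_h",
     None, None, "", "transport", "", None),
    ("T_nh4_ch", "ammonium transport", "nh4_c <-> nh4_h", None, None, "",
     "transport", "", None),
    # ------------------------------------------------- nitrogen assimilation
    ("NR_c", "nitrate reductase", "no3_c + nadh_c -> no2_c + nad_c + h2o_c",
     None, None, "g_nr1 or g_nr2", "nitrogen_assimilation", "1.7.1.1",
     "nitrate_reductase"),
    ("NiR_h", "ferredoxin-nitrite reductase (NADPH-lumped)",
     "no2_h + 3 nadph_h -> nh4_h + 3 nadp_h + 2 h2o_h", None, None, "g_nir1",
     "nitrogen_assimilation", "1.7.7.1", None),
    ("GS_h", "chloroplast glutamine synthetase",
     "glu_h + nh4_h + atp_h -> gln_h + adp_h + pi_h", None, None, "g_gs2",
     "nitrogen_assimilation", "6.3.1.2", None),
    ("GOGAT_h", "ferredoxin-glutamate synthase (NADPH-lumped)",
     "gln_h + akg_h + nadph_h -> 2 glu_h + nadp_h", None, None, "g_gogat1",
     "nitrogen_assimilation", "1.4.7.1", "fd_gogat"),
    ("GS_c", "cytosolic glutamine synthetase",
     "glu_c + nh4_c + atp_c -> gln_c + adp_c + pi_c", None, None, "g_gs1",
     "nitrogen_assimilation", "6.3.1.2", None),
    ("GOGAT_c", "NADH-glutamate synthase",
     "gln_c + akg_c + nadh_c -> 2 glu_c + nad_c", None, None, "g_gogat2",
     "nitrogen_assimilation", "1.4.1.14", None),
    # ---------------------------------------------------- pentose phosphate
    ("G6PD_c", "glucose-6-phosphate dehydrogenase (+ lactonase, lumped)",
     "g6p_c + nadp_c -> pg6_c + nadph_c", None, None, "g_g6pd1 or g_g6pd2",
     "pentose_phosphate", "1.1.1.49", "g6pd"),
    ("PGD_c", "6-phosphogluconate dehydrogenase",
     "pg6_c + nadp_c -> ru5p_c + co2_c + nadph_c", None, None,
     "g_6pgd1 or g_6pgd2", "pentose_phosphate", "1.1.1.44", "pgd6"),
    ("NOPPP_c", "non-oxidative pentose phosphate segment (lumped)",
     "3 ru5p_c -> 2 f6p_c + gap_c", None, None, "g_tktC",
     "pentose_phosphate", "", None),
    # ------------------------------------------------------------ amino acid
    ("AspAT_c", "aspartate aminotransferase",
     "oaa_c + glu_c <-> asp_c + akg_c", None, None, "g_aspat1", "amino_acid",
     "2.6.1.1", None),
    ("AlaAT_c", "alanine aminotransferase",
     "pyr_c + glu_c <-> ala_c + akg_c", None, None, "g_alaat1", "amino_acid",
     "2.6.1.2", None),
    ("SULFA_c", "assimilatory sulfate reduction (ATP-sulfurylase..SiR, lumped)",
     "so4_c + 2 atp_c + 4 nadph_c -> h2s_c + 2 adp_c + 2 pi_c + 4 nadp_c",
     None, None, "g_aps1", "amino_acid", "", None),
    ("CYS_c", "cysteine synthesis (OAS pathway, lumped)",
     "ser_c + h2s_c -> cys_c + h2o_c", None, None, "g_oastl1", "amino_acid",
     "2.5.1.47", None),
    ("PROTSYN_c", "protein synthesis (mean residue, incl. translation ATP)",
     "0.18 glu_c + 0.1 gln_c + 0.16 asp_c + 0.2 ala_c + 0.14 ser_c + "
     "0.16 gly_c + 0.06 cys_c + 4.3 atp_c -> protpool_c + 4.3 adp_c + 4.3 pi_c",
     None, None, "", "amino_acid", "", None),
    # ------------------------------------------------------------ fatty acid
    ("FAS_h", "plastid fatty-acid synthesis to palmitate "
     "(PDH + ACCase + FAS, lumped; PDH NADH credited against NADPH demand)",
     "8 pyr_h + 7 atp_h + 6 nadph_h -> palm_h + 8 co2_h + 7 adp_h + 7 pi_h + "
     "6 nadp_h", None, None, "g_accA and g_fab1", "fatty_acid", "", None),
    ("T_palm_hc", "acyl export from chloroplast", "palm_h -> palm_c",
     None, None, "", "transport", "", None),
    # ---------------------------------------------------------- maintenance
    ("MAINT_m", "maintenance ATP demand (dark respiration)",
     "atp_m + h2o_m -> adp_m + pi_m", None, None, "", "maintenance", "",
     "maintenance"),
]
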