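{
 "metabolites": [
  {
   "id": "glc_e",
   "name": "",
   "compartment": "e"
  },
  {
   "id": "nh4_e",
   "name": "",
   "compartment": "e"
  },
  {
   "id": "co2_e",
   "name": "",
   "compartment": "e"
  },
  {
   "id": "ac_e",
   "name": "",
   "compartment": "e"
  },
  {
   "id": "gol_e",
   "name": "",
   "compartment": "e"
  },
  {
   "id": "g6p_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "pyr_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "accoa_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "oaa_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "cit_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "akg_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "nh4_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "co2_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "ac_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "gol_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "fut1_c",
   "name": "",
   "compartment": "c"
  },
  {
   "id": "fut2_c",
   "name": "",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_glc_e",
   "name": "",
   "metabolites": {
    "glc_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Exchange"
  },
  {
   "id": "EX_nh4_e",
   "name": "",
   "metabolites": {
    "nh4_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Exchange"
  },
  {
   "id": "EX_co2_e",
   "name": "",
   "metabolites": {
    "co2_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Exchange"
  },
  {
   "id": "EX_ac_e",
   "name": "",
   "metabolites": {
    "ac_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Exchange"
  },
  {
   "id": "EX_gol_e",
   "name": "",
   "metabolites": {
    "gol_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Exchange"
  },
  {
   "id": "GLCpts",
   "name": "",
   "metabolites": {
    "glc_e": -1.0,
    "g6p_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_ptsG and g_ptsH",
   "subsystem": "Transport"
  },
  {
   "id": "NH4t",
   "name": "",
   "metabolites": {
    "nh4_e": -1.0,
    "nh4_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_amtB",
   "subsystem": "Transport"
  },
  {
   "id": "CO2t",
   "name": "",
   "metabolites": {
    "co2_e": 1.0,
    "co2_c": -1.0
   },
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Transport"
  },
  {
   "id": "PYK",
   "name": "",
   "metabolites": {
    "g6p_c": -1.0,
    "pyr_c": 2.0
   },
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_pykF or g_pykA",
   "subsystem": "Glycolysis"
  },
  {
   "id": "PDH",
   "name": "",
   "metabolites": {
    "pyr_c": -1.0,
    "accoa_c": 1.0,
    "co2_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_aceE and g_aceF and g_lpd",
   "subsystem": "Glycolysis"
  },
  {
   "id": "CS",
   "name": "",
   "metabolites": {
    "accoa_c": -1.0,
    "oaa_c": -1.0,
    "cit_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_gltA",
   "subsystem": "TCA"
  },
  {
   "id": "CITDH",
   "name": "",
   "metabolites": {
    "cit_c": -1.0,
    "akg_c": 1.0,
    "co2_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_icd",
   "subsystem": "TCA"
  },
  {
   "id": "AKGDH",
   "name": "",
   "metabolites": {
    "oaa_c": 1.0,
    "akg_c": -1.0,
    "co2_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_sucA and g_sucB",
   "subsystem": "TCA"
  },
  {
   "id": "PPC",
   "name": "",
   "metabolites": {
    "pyr_c": -1.0,
    "oaa_c": 1.0,
    "co2_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_ppc",
   "subsystem": "Anaplerotic"
  },
  {
   "id": "ICL",
   "name": "",
   "metabolites": {
    "accoa_c": -2.0,
    "oaa_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_aceA and g_aceB",
   "subsystem": "Glyoxylate shunt"
  },
  {
   "id": "PCK",
   "name": "",
   "metabolites": {
    "pyr_c": 1.0,
    "oaa_c": -1.0,
    "co2_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_pck",
   "subsystem": "Gluconeogenesis"
  },
  {
   "id": "ACSYN",
   "name": "",
   "metabolites": {
    "g6p_c": -1.0,
    "ac_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_pta or g_ackA",
   "subsystem": "Overflow"
  },
  {
   "id": "ACt",
   "name": "",
   "metabolites": {
    "ac_e": 1.0,
    "ac_c": -1.0
   },
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_actP",
   "subsystem": "Transport"
  },
  {
   "id": "ACS",
   "name": "",
   "metabolites": {
    "accoa_c": 1.0,
    "co2_c": 1.0,
    "ac_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_acs",
   "subsystem": "Overflow"
  },
  {
   "id": "GOLSYN",
   "name": "",
   "metabolites": {
    "pyr_c": -1.0,
    "gol_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_gpsA",
   "subsystem": "Overflow"
  },
  {
   "id": "GOLt",
   "name": "",
   "metabolites": {
    "gol_e": 1.0,
    "gol_c": -1.0
   },
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_glpF",
   "subsystem": "Transport"
  },
  {
   "id": "GOLCAT",
   "name": "",
   "metabolites": {
    "pyr_c": 1.0,
    "gol_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_glpK and g_glpD",
   "subsystem": "Overflow"
  },
  {
   "id": "FUT1",
   "name": "",
   "metabolites": {
    "g6p_c": -1.0,
    "fut1_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_fut1",
   "subsystem": "Futile"
  },
  {
   "id": "FUT2",
   "name": "",
   "metabolites": {
    "fut1_c": -1.0,
    "fut2_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_fut2",
   "subsystem": "Futile"
  },
  {
   "id": "FUT3",
   "name": "",
   "metabolites": {
    "g6p_c": 1.0,
    "fut2_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g_fut3",
   "subsystem": "Futile"
  },
  {
   "id": "BIOMASS",
   "name": "",
   "metabolites": {
    "g6p_c": -0.5,
    "akg_c": -0.5,
    "nh4_c": -0.2
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "subsystem": "Biomass",
   "objective_coefficient": 1.0
  }
 ],
 "genes": [
  {
   "id": "g_aceA"
  },
  {
   "id": "g_aceB"
  },
  {
   "id": "g_aceE"
  },
  {
   "id": "g_aceF"
  },
  {
   "id": "g_ackA"
  },
  {
   "id": "g_acs"
  },
  {
   "id": "g_actP"
  },
  {
   "id": "g_amtB"
  },
  {
   "id": "g_fut1"
  },
  {
   "id": "g_fut2"
  },
  {
   "id": "g_fut3"
  },
  {
   "id": "g_glpD"
  },
  {
   "id": "g_glpF"
  },
  {
   "id": "g_glpK"
  },
  {
   "id": "g_gltA"
  },
  {
   "id": "g_gpsA"
  },
  {
   "id": "g_icd"
  },
  {
   "id": "g_lpd"
  },
  {
   "id": "g_pck"
  },
  {
   "id": "g_ppc"
  },
  {
   "id": "g_pta"
  },
  {
   "id": "g_ptsG"
  },
  {
   "id": "g_ptsH"
  },
  {
   "id": "g_pykA"
  },
  {
   "id": "g_pykF"
  },
  {
   "id": "g_sucA"
  },
  {
   "id": "g_sucB"
  }
 ],
 "id": "crossfeed_model",
 "version": "1"
}
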