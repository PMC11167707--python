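{
  "description": "Worked GBM example: degree-hub nodes of a published ceRNA network (A), the constituent nodes of its lncRNA-miRNA-seed subnetwork (B), their printed intersection, the seed genes, and the three named MS4A6A regulatory axes.",
  "hub_nodes": [
    "hsa-miR-210-3p", "hsa-miR-4701-3p", "hsa-miR-27a-3p", "hsa-miR-15b-5p",
    "hsa-miR-485-5p", "hsa-miR-195-5p", "hsa-miR-23a-3p", "hsa-miR-139-5p",
    "hsa-miR-497-5p", "hsa-miR-432-5p", "GAS5", "hsa-miR-433-3p",
    "hsa-let-7g-5p", "PART1", "APBA1", "hsa-miR-98-5p", "SNHG29",
    "LINC00507", "LINC00641", "PABPC1L2A", "HTR3B", "SEC31B", "GPR26",
    "PTER", "RPL32"
  ],
  "seed_network_nodes": [
    "AL161785.1", "GAS5", "PCED1B-AS1", "LINC02611", "AL021395.1",
    "LY86-AS1", "LINC00507", "LINC01378", "AL049775.1", "LINC01616",
    "TRHDE-AS1", "hsa-miR-139-5p", "hsa-miR-432-5p", "hsa-miR-433-3p",
    "hsa-miR-485-5p", "hsa-miR-27a-3p", "hsa-miR-4701-3p", "hsa-miR-15b-5p",
    "MS4A6A", "RPL9", "CD74", "CD300A", "GABRA6", "HRH3", "MAPK9"
  ],
  "published_intersection": [
    "hsa-miR-432-5p", "hsa-miR-485-5p", "hsa-miR-433-3p", "hsa-miR-4701-3p",
    "hsa-miR-27a-3p", "hsa-miR-139-5p", "hsa-miR-15b-5p", "LINC00507", "GAS5"
  ],
  "seed_genes": ["MS4A6A", "CD74", "CD300A", "RPL9", "GABRA6", "HRH3", "MAPK9"],
  "lncrnas": [
    "AL161785.1", "LINC02611", "PCED1B-AS1", "GAS5", "LINC01616",
    "AL021395.1", "LINC00507", "LINC01378", "AL049775.1", "LY86-AS1",
    "TRHDE-AS1"
  ],
  "mirnas": [
    "hsa-miR-139-5p", "hsa-miR-432-5p", "hsa-miR-433-3p", "hsa-miR-485-5p",
    "hsa-miR-27a-3p", "hsa-miR-4701-3p", "hsa-miR-15b-5p"
  ],
  "named_axes": [
    ["AL161785.1", "hsa-miR-139-5p", "MS4A6A"],
    ["LINC02611", "hsa-miR-139-5p", "MS4A6A"],
    ["PCED1B-AS1", "hsa-miR-433-3p", "MS4A6A"]
  ]
}
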