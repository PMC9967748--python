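# Oncogenic signature pathways commonly interrogated in papillary thyroid
# carcinoma enrichment analyses. These are MSigDB set names only: MSigDB
# content is not redistributed here. Download the gene members from
# https://www.gsea-msigdb.org/gsea/msigdb/ and assemble a GMT file
# (one line per set: name, description, tab-separated gene symbols) for use
# with mycoarch's gsea stage.
PID_PI3KCI_AKT_PATHWAY
BIOCARTA_RAS_PATHWAY
REACTOME_SIGNALING_BY_MODERATE_KINASE_ACTIVITY_BRAF_MUTANTS
KEGG_P53_SIGNALING_PATHWAY
REACTOME_RET_SIGNALING
REACTOME_ONCOGENIC_MAPK_SIGNALING
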