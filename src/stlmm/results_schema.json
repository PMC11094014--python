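{
  "description": "Column order and meaning of the results.tsv written by `stlmm run` and de_testing.results_to_frame.",
  "columns": [
    {"name": "gene_id", "type": "string", "meaning": "gene identifier"},
    {"name": "comparison", "type": "string", "meaning": "'<label> vs rest' or '<labelA> vs <labelB>'"},
    {"name": "n_units", "type": "int", "meaning": "sampling units entering the test (pair-restricted for pairwise)"},
    {"name": "estimate", "type": "float", "meaning": "log-expression difference of the focal group (spatial GLS estimate when the spatial fit converged, OLS otherwise)"},
    {"name": "se", "type": "float", "meaning": "standard error of the estimate (Kenward-Roger adjusted for spatial fits)"},
    {"name": "statistic", "type": "float", "meaning": "Wald statistic estimate/se"},
    {"name": "p_nonspatial", "type": "float|missing", "meaning": "two-sided p from the non-spatial model, t(n-2) reference; equals the pooled two-sample t-test"},
    {"name": "p_spatial", "type": "float|missing", "meaning": "two-sided p from the spatial mixed model, t reference with Satterthwaite df; missing when the fit did not converge"},
    {"name": "fdr_nonspatial", "type": "float|missing", "meaning": "Benjamini-Hochberg adjusted p_nonspatial within the FDR family"},
    {"name": "fdr_spatial", "type": "float|missing", "meaning": "Benjamini-Hochberg adjusted p_spatial within the FDR family"},
    {"name": "aic_nonspatial", "type": "float", "meaning": "2k - 2 ln(L) of the non-spatial fit, k = 3"},
    {"name": "aic_spatial", "type": "float|missing", "meaning": "2k - 2 ln(L) of the spatial fit at the fitted parameters, k = 5"},
    {"name": "spatial_favored", "type": "bool|missing", "meaning": "aic_spatial < aic_nonspatial; ties favor the non-spatial model; missing without spatial convergence"},
    {"name": "mean_expr", "type": "float", "meaning": "mean normalized log-expression of the gene over all units"},
    {"name": "stratum", "type": "high|low", "meaning": "gene expression stratum relative to the median gene mean"},
    {"name": "converged_spatial", "type": "bool", "meaning": "spatial REML/ML optimization reached convergence"}
  ]
}
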