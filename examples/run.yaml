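# Fully-populated pipeline configuration template.
# Either keep the `simulate` block (synthetic paired cohorts) or replace it
# with an `inputs` block of file paths (see README).
seed: 1
outdir: scratch/run1

simulate:
  bulk:
    n_genes: 2000
    n_samples: 200
    n_signature_genes: 50      # genes per planted stromal/immune signature
    n_driver_genes: 30         # planted receptor/ligand stroma drivers
    n_rl_decoys: 150           # signal-free receptor/ligand genes
    driver_log2fc: 1.5         # subgroup shift of drivers, log2 units
    driver_stroma_coupling: 1.2  # log2 units per unit latent stromal fraction
    signature_coupling: 2.0
    noise_sd: 0.5
  sc:
    n_genes: 1500
    n_tumours: 10
    cells_per_tumour: [300, 300]
    detection_coupling: 6.0    # logistic slope of associate detection vs activity
    potential_coupling: 1.5    # library-size scaling of activity

thresholds:
  fc_min: 2.0            # linear fold-change cutoff (strict) in the DGE screen
  r_assoc: 0.2           # minimum |Pearson r| with stromal score (strict)
  alpha: 0.05            # significance level applied throughout
  r_min_bulk: 0.6        # bulk co-expression network edge threshold
  r_min_sc: 0.2          # single-cell network edge threshold
  active_min: 5          # stroma-active iff associate count > 5
  inactive_max: 2        # stroma-inactive iff associate count < 2
  sc_expressed_frac: 0.01  # drop genes detected in < 1% of cells
  ssgsea_alpha: 0.25     # ssGSEA rank-weight exponent
  top_k: 200             # genes in the developmental-potential signature

enriched_subgroup: SHH       # stroma-enriched contrast target
suppressed_subgroup: Group3  # stroma-suppressed contrast target
stromal_signature: stromal   # GMT set used for the stromal score
immune_signature: immune
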