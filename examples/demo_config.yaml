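# Demo cohort: 3 subjects on a reduced two-chromosome genome at the default
# 4-kb probe density and noise levels.  Completes in well under a minute.
seed: 7
sim:
  n_subjects: 3
  genome: {n_chroms: 2, chrom_mb: 60.0, spacing: 4000}
  um_range: [1, 3]
  pt_range: [1, 2]
  p_aberrant_um: 1.0
  aberrations_per_um: 0.0
  size_mb_range: [10.0, 25.0]
  fraction_range: [0.2, 0.6]
  propagation_prob: 1.0
qc:
  # events span a sizeable share of this reduced genome, so estimate array
  # noise from probe-to-probe differences rather than the global sd
  dev_method: diff
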