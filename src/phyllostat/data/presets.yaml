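# Genotype presets for the synthetic-data generators.
#
# torsion_mean_deg values marked "measured" come from epidermal cell-file
# measurements (counterclockwise positive); the remaining numbers are
# package defaults chosen to reproduce the qualitative ordering of the
# phenotypes (wild type most regular; plt mutants noisier, longer
# internodes, earlier bolting), since the fitted experimental distributions
# are not available as tables.
col0:
  delta_i_sd: 10.0          # deg, initiation noise around the golden angle
  decussate_rate: 0.0       # per-plant probability of a decussate episode
  m_motif_rate: 0.01        # per-eligible-triplet organ-swap probability
  torsion_mean_deg: 0.6     # measured, counterclockwise
  torsion_sd_deg: 0.6
  internode_scale: 1.0
  bolting_advance_days: 0.0
  rosette:
    amplitude: 42.5         # deg; first leaf pair starts near 180
    damping: 0.55           # per-pair exponential decay rate
    noise_sd: 8.0           # deg
plt_triple:                 # plt3 plt5 plt7-like
  delta_i_sd: 17.0
  decussate_rate: 0.10      # decussate episodes in c. 10% of young meristems
  m_motif_rate: 0.02
  torsion_mean_deg: 0.6     # measured (same distribution as wild type)
  torsion_sd_deg: 0.6
  internode_scale: 1.35
  bolting_advance_days: 4.0
  rosette:
    amplitude: 42.5
    damping: 0.30           # slower damping: larger oscillations at pairs 5-6
    noise_sd: 14.0
spr2:                       # spr2-2-like enhanced counterclockwise torsion
  delta_i_sd: 10.0
  decussate_rate: 0.0
  m_motif_rate: 0.01
  torsion_mean_deg: 1.7     # measured
  torsion_sd_deg: 0.8
  internode_scale: 1.0
  bolting_advance_days: 0.0
  rosette:
    amplitude: 42.5
    damping: 0.55
    noise_sd: 8.0
tor2:                       # tor2-like clockwise (negative) torsion
  delta_i_sd: 10.0
  decussate_rate: 0.0
  m_motif_rate: 0.01
  torsion_mean_deg: -1.1    # measured, clockwise
  torsion_sd_deg: 0.8
  internode_scale: 1.0
  bolting_advance_days: 0.0
  rosette:
    amplitude: 42.5
    damping: 0.55
    noise_sd: 8.0
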