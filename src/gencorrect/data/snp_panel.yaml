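# Default SNP-effect panel for multiplicative genetic correction of serum
# AFP, CA19-9 and CEA in an elderly Chinese cohort.
#
# Effects are keyed by the count of the effect-INCREASING allele, whose
# population frequency is `effect_allele_freq` and whose per-copy
# multiplicative effect on the geometric-mean level is `allelic_effect`.
# When `effect_allele_is_listed` is false the published listed allele is the
# level-decreasing one; the increasing allele's base is then unknown and is
# written "*" ("the allele other than `other_allele`"), except rs1047781
# where the increasing allele is the T of the known A>T substitution.
#
# `printed_triple` is the published genotype-effect triple (e0, e1, e2) for
# 0/1/2 copies of the effect-increasing allele, rounded to 2 dp. Loading
# recomputes exact triples from (allelic_effect, effect_allele_freq) under
# the Hardy-Weinberg mean-one normalization; the printed values are kept as
# reference metadata only.
panels:
  AFP:
    - rsid: rs12506899
      chrom: "4"
      position_bp: 74538147
      listed_allele: T
      effect_allele_is_listed: true
      effect_allele_freq: 0.33
      allelic_effect: 1.08
      printed_triple: [0.95, 1.02, 1.10]
    - rsid: rs2251844
      chrom: "15"
      position_bp: 41623770
      listed_allele: T
      effect_allele_is_listed: false
      effect_allele_freq: 0.47
      allelic_effect: 1.10
      printed_triple: [0.92, 1.00, 1.11]
  CA19-9:
    - rsid: rs17271883
      chrom: "19"
      position_bp: 5785212
      listed_allele: A
      effect_allele_is_listed: false
      effect_allele_freq: 0.44
      allelic_effect: 1.29
      printed_triple: [0.78, 1.01, 1.31]
    - rsid: rs3760775
      chrom: "19"
      position_bp: 5792356
      listed_allele: G
      effect_allele_is_listed: true
      effect_allele_freq: 0.25
      allelic_effect: 1.49
      printed_triple: [0.79, 1.18, 1.76]
    - rsid: rs265548
      chrom: "19"
      position_bp: 17763334
      listed_allele: T
      effect_allele_is_listed: true
      effect_allele_freq: 0.23
      allelic_effect: 1.04
      printed_triple: [0.98, 1.02, 1.07]
    - rsid: rs1047781
      chrom: "19"
      position_bp: 53898443
      listed_allele: A
      effect_allele_is_listed: false
      effect_allele: T
      effect_allele_freq: 0.40
      allelic_effect: 1.38
      printed_triple: [0.76, 1.04, 1.43]
  CEA:
    - rsid: rs8176749
      chrom: "9"
      position_bp: 135121009
      listed_allele: C
      effect_allele_is_listed: false
      effect_allele_freq: 0.21
      allelic_effect: 1.17
      printed_triple: [0.93, 1.09, 1.28]
    - rsid: rs8176720
      chrom: "9"
      position_bp: 135122694
      listed_allele: T
      effect_allele_is_listed: false
      effect_allele_freq: 0.45
      allelic_effect: 1.08
      printed_triple: [0.93, 1.01, 1.09]
    - rsid: rs3670775
      chrom: "19"
      position_bp: 5792356
      listed_allele: G
      effect_allele_is_listed: false
      effect_allele_freq: 0.25
      allelic_effect: 1.06
      printed_triple: [0.97, 1.03, 1.09]
      notes:
        - "shares chr19:5,792,356 and frequency 0.25 with rs3760775 (CA19-9 panel); likely a published rsid typo, kept as printed"
    - rsid: rs1047781
      chrom: "19"
      position_bp: 53898443
      listed_allele: A
      effect_allele_is_listed: false
      effect_allele: T
      effect_allele_freq: 0.40
      allelic_effect: 1.17
      printed_triple: [0.88, 1.03, 1.20]
    - rsid: rs441810
      chrom: "21"
      position_bp: 41620777
      listed_allele: A
      effect_allele_is_listed: false
      effect_allele_freq: 0.18
      allelic_effect: 1.01
      printed_triple: [1.00, 1.01, 1.02]
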