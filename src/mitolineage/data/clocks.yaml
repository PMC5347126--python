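# Packaged molecular-clock calibrations for whole human mitogenomes.
# soares_whole_mtdna: 'evolutionary' whole-genome rate, one substitution
#   every 3,624 years.
# fu_ancient_dna: ancient-DNA-calibrated rate in substitutions/site/year
#   with its 95% HPD bounds, applied to the 16,569-bp genome.
- name: soares_whole_mtdna
  mode: years_per_substitution
  value: 3624.0
- name: fu_ancient_dna
  mode: per_site_per_year
  value: 2.67e-8
  low: 2.16e-8
  high: 3.16e-8
  genome_length: 16569
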