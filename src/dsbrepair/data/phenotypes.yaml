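# Generic cell-line phenotype fixtures.
#
# genome_gbp is the total unreplicated (G1) DNA content in Gbp: 6.1 Gbp for a
# diploid human cell (so that 5.738 DSB/Gy/Gbp gives ~35 DSB/Gy).  Hamster
# values are representative of Chinese hamster lines (V79/CHO-like, 2n ~ 21-22
# chromosomes, ~4.7 Gbp diploid) and should be overridden per line where known.
- name: human-normal
  genome_gbp: 6.1
  n_chromosomes: 46
  nhej_competent: true
  hr_competent: true
  g1_arrest_competent: true
  phase: asynchronous
- name: hamster
  genome_gbp: 4.7
  n_chromosomes: 21
  nhej_competent: true
  hr_competent: true
  g1_arrest_competent: false
  phase: asynchronous
- name: hamster-nhej-deficient
  genome_gbp: 4.7
  n_chromosomes: 21
  nhej_competent: false
  hr_competent: true
  g1_arrest_competent: false
  phase: asynchronous
- name: hamster-hr-deficient
  genome_gbp: 4.7
  n_chromosomes: 21
  nhej_competent: true
  hr_competent: false
  g1_arrest_competent: false
  phase: asynchronous
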