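# Full pipeline configuration: simulate both slots, analyse, compare.
reference:
  preset: DH-SCEN
  seed: 1
future:
  preset: DH-TMED
  seed: 2
slots:
  reference: {label: SCEN, start_year: 1981, end_year: 2010}
  future: {label: TMED, start_year: 2041, end_year: 2070}
crop:
  t_base: 2.5
  t_h: 2100
  sowing_month: 9
  sowing_day: 15
  smoothing_window: 5
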