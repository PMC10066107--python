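# Product presets: published population estimates for the convolution model
# (apparent disposition CL/F, V/F with F fixed at 1; release fractions FF are
# dimensionless fractions of dose). PP12M is a hypothetical once-a-year depot
# whose release function was designed to match PP3M steady-state exposure; it
# reuses the PP3M disposition.
ER:
  release: {family: weibull2, FF: 0.309, TD: 0.864, SS: 8.71, TD1: 1.54, SS1: 0.395}
  disposition: {CL: 15.13, V: 446.0}
  doses_mg: [3, 6, 9, 12, 15]
  interval_h: 24.0
  schedule_h: [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0,
               10.0, 12.0, 16.0, 20.0, 24.0, 30.0, 36.0, 48.0, 60.0, 72.0, 96.0]
PP1M:
  release: {family: weibull2, FF: 0.355, TD: 9.45, SS: 3.14, TD1: 3.61, SS1: 2.68}
  disposition: {CL: 5.04, V: 6080.0}
  doses_mg: [25, 50, 100, 150]
  interval_h: 720.0
  schedule_h: [1.0, 2.0, 4.0, 6.0, 9.0, 12.0, 16.0, 20.0, 24.0, 36.0, 48.0, 72.0,
               96.0, 120.0, 168.0, 240.0, 336.0, 432.0, 504.0, 600.0, 720.0, 840.0,
               960.0, 1080.0, 1200.0, 1320.0, 1440.0, 1560.0, 1680.0, 1800.0,
               1920.0, 2040.0, 2160.0]
PP3M:
  release: {family: weibull2, FF: 0.676, TD: 12.6, SS: 1.66, TD1: 6.32, SS1: 2.16}
  disposition: {CL: 4.38, V: 11700.0}
  doses_mg: [175, 300, 450, 525]
  interval_h: 2160.0
  # ~40 samples over one year, dense across the release window (< 100 h) so
  # that both Weibull processes of the biphasic release are identifiable
  schedule_h: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 12.0, 14.0, 16.0,
               18.0, 20.0, 24.0, 28.0, 32.0, 36.0, 40.0, 48.0, 56.0, 64.0, 72.0,
               84.0, 96.0, 120.0, 168.0, 240.0, 360.0, 504.0, 720.0, 1080.0, 1440.0,
               2160.0, 2880.0, 4320.0, 5760.0, 7200.0, 8760.0]
PP12M:
  release: {family: weibull2, FF: 0.2768, TD: 22.0, SS: 1.6, TD1: 180.0, SS1: 2.13}
  disposition: {CL: 4.38, V: 11700.0}
  doses_mg: [1600]
  interval_h: 8760.0
  schedule_h: [1.0, 6.0, 12.0, 24.0, 48.0, 96.0, 168.0, 240.0, 336.0, 504.0, 720.0,
               1080.0, 1440.0, 2160.0, 2880.0, 3600.0, 4320.0, 5040.0, 5760.0,
               6480.0, 7200.0, 7920.0, 8760.0]
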