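# Default emission-factor configuration.
#
# ef_m  : manufacture emission factors, kg CO2-eq per kg fertilizer-N,
#         covering fossil-fuel mining/transport, ammonia synthesis and
#         conversion to each product (life-cycle factors for China).
# ef_d  : direct soil N2O emission factors, kg N2O-N per kg N applied,
#         specific to agricultural region and crop.  A missing
#         (region, crop) entry means no factor exists (e.g. no wheat
#         factor for Northeast China) and any lookup must fail loudly.
# gwp_n2o : 100-year global warming potential of N2O relative to CO2.
# n_to_n2o: mass conversion from N to N2O; "44/28" is parsed as an
#           exact rational.
gwp_n2o: 298.0
n_to_n2o: 44/28
ef_m:
  urea: 8.1
  cf: 7.4
  dap: 10.3
  abc: 7.2
ef_d:
  NEC:
    maize: 0.0051
  NC:
    wheat: 0.0028
    maize: 0.0070
  MLYR:
    wheat: 0.0086
    maize: 0.0067
  NWC:
    wheat: 0.0032
    maize: 0.0057
  SSWC:
    wheat: 0.0050
    maize: 0.0047
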