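analysis,cost_nontdm,cost_tdm,qaly_nontdm,qaly_tdm,icer
base_case,12275.89,12590.69,8.66,9.09,732.91
newly_diagnosed,12448.09,10862.02,8.85,9.71,dominant
refractory,11775.38,13363.39,8.56,8.8,6696.31
one_year_tdm,12189.19,12611.53,8.67,9.08,1012.3
horizon_1y,2224.35,2484.55,1.48,1.54,4112.92
horizon_5y,6614.82,6964.91,4.59,4.83,1480.36
horizon_10y,10121.84,10464.1,7.12,7.47,957.49
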