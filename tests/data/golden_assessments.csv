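patient_id,comparison,baseline_date,follow_date,status,delta_d_mm,delta_v_cm3,delta_v_pct,triggered_by,diameter_basis_switched
phantom-001,consecutive,2011-01-01,2012-01-01,growth,1.7758,0.5924,33.7121,volume_pct,False
phantom-001,consecutive,2012-01-01,2013-01-01,growth,3.5579,1.5319,65.1994,diameter|volume_abs|volume_pct,False
phantom-001,index_vs_latest,2011-01-01,2013-01-01,growth,5.3337,2.1243,120.8916,diameter|volume_abs|volume_pct,False
phantom-001,penultimate_vs_latest,2012-01-01,2013-01-01,growth,3.5579,1.5319,65.1994,diameter|volume_abs|volume_pct,False
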