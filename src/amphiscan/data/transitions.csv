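# Default SRM transition library for amphidinol detection.
# Q1 = sodium-adduct precursor m/z; Q3 = hydrophilic-arm fragment produced by
# the C1/C1' cleavage (after desulfation for sulfated variants). Retention
# times in minutes. Only the eight ARC variants have all parameters
# recoverable from the published description; extend this file with the
# remaining known AM transitions from your instrument method.
variant_name,q1_mz,q3_mz,rt_min,sulfated
ARC-1,1226,834,3.89,false
ARC-2,1266,754,3.03,true
ARC-3,1358,932,2.90,false
ARC-4,1398,886,2.93,true
ARC-5,1426,1034,3.87,false
ARC-6,1446,928,3.20,true
ARC-7,1506,1080,4.35,false
ARC-8,1608,1062,3.26,true
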