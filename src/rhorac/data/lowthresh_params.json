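{
 "schema_version": 1,
 "units": {
  "concentration": "molecules",
  "time": "hour"
 },
 "g_rac1": 6000.0,
 "g_rhoa_basal": 60.0,
 "g_rhoa_exc": 386.0,
 "k_rac1": 1.0,
 "k_rhoa": 1.0,
 "rhoa_selfact": {
  "threshold": 390.0,
  "coefficient": 6,
  "fold_change": 5.0
 },
 "loading_rac1": {
  "intrinsic_rate": 1.349,
  "regulators": [
   {
    "species": "rac1_gtp",
    "threshold": 560.0,
    "coefficient": 8,
    "fold_change": 12.0
   },
   {
    "species": "rhoa_gtp",
    "threshold": 300.0,
    "coefficient": 4,
    "fold_change": 0.21
   },
   {
    "species": "grb2",
    "threshold": 250000.0,
    "coefficient": 2,
    "fold_change": 30.0
   }
  ]
 },
 "loading_rhoa": {
  "intrinsic_rate": 6.0,
  "regulators": [
   {
    "species": "rac1_gtp",
    "threshold": 300.0,
    "coefficient": 4,
    "fold_change": 0.45
   },
   {
    "species": "gab1",
    "threshold": 250000.0,
    "coefficient": 2,
    "fold_change": 4.0
   }
  ]
 },
 "hydrolysis_rac1": {
  "intrinsic_rate": 8.0,
  "regulators": []
 },
 "hydrolysis_rhoa": {
  "intrinsic_rate": 1.0,
  "regulators": []
 },
 "mirna_rhoa": {
  "half_effect": 300.0,
  "coefficient": 1
 },
 "mirna_rac1": {
  "half_effect": 300.0,
  "coefficient": 1
 },
 "gdi_on": 200.0,
 "gdi_off": 100.0,
 "noise_level": 240.0,
 "thresh_rac1_high": 377.66,
 "thresh_rhoa_high": 373.37
}
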