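{
 "segments": {
  "ntail": "NDKDEETKPSGEEQAEEQQDTPSEQDDEEKETDEPTSPDPNSDGSKPGSP",
  "core": "ATMMNGLMFGLFCSMIMIGGVAIATLGSTDTGYSTGFVCFAIISATDKWIAIGNIGGMYVFIIFVLQMSSLMPCAALQNNVTYIVPHITSGLGINGNQNPAVSVTITYYFSGGLNATQV",
  "partial_core": "TAEGQDKADKEQEKKGSGAQASGKGEGSAGR",
  "extension": "DESPGKNTNESDKG"
 },
 "rossmann_offset": 22,
 "variants": {
  "short_core": "ATMMNGLMFGLYCSMITIGVVAGATAGSTWTGYSTVFVFFAIQSATTLQIAIGNIGGMYVFIIFVLQGSSLFPCAALQNTVTYIVPNIMSGLGINGDWNPAASVTGTYYFSAGMNATEV",
  "truncated_core": "ATMMNGNMFGLFCSMIMIGGVAQATLGSTDTGYSTGGQCFAIIVATDKWIAIGNIGGMYVFIIFVLQMSSLMPCAALQANVTYIVPHITSGLGINGNQNPAVSVTITYYFSGGLNATQV"
 },
 "markers": {
  "DCX": "WTAPYGSWYPNPHATYNNTHGSGGAGSSGHSGHHNSTSNNHYHANTNWLTGTSWAAYTHWHSHWWNWNNAYGWWWTLHWT",
  "EFh": "TSFSGEEYNYFDEEDYNDSESDENDFYNDNFDEFFYEGLYNYDGYFNTFSYGTSTNGSYN",
  "IQ": "ILSMQQMAMLMIATQAILILILI",
  "Kelch": "PWYSWTPGGPGPTGGSYWVPYSPTYVNTVSTWNYYPGGWWWTWTSTVWGV",
  "Znf_BBOX": "SHCSCTPSTLGGSEGPHHGSSLPTTCPHSLSTLHEHTSGP"
 }
}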