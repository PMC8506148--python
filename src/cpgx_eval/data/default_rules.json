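{
 "CYP2B6": {
  "rule_kind": "categorical",
  "altered_categories": ["intermediate", "poor"]
 },
 "CYP2C19": {
  "rule_kind": "categorical",
  "altered_categories": [
   "ultrarapid",
   "rapid",
   "likely intermediate",
   "intermediate",
   "likely poor",
   "poor"
  ]
 },
 "CYP2C9": {
  "rule_kind": "activity_interval",
  "normal_interval": [2, null]
 },
 "CYP2D6": {
  "rule_kind": "activity_interval",
  "normal_interval": [1.25, 2.25]
 },
 "CYP3A5": {
  "rule_kind": "categorical",
  "altered_categories": ["intermediate", "extensive"]
 }
}
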