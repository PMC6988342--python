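{
 "beta": [
  0.0,
  0.1,
  0.2,
  0.3,
  0.4,
  0.5,
  0.6,
  0.7,
  0.8,
  0.9,
  1.0,
  1.1,
  1.2,
  1.3,
  1.4,
  1.5,
  1.6,
  1.7,
  1.8,
  1.9,
  2.0,
  2.1,
  2.2,
  2.3,
  2.4,
  2.5,
  2.6,
  2.7,
  2.8,
  2.9,
  3.0
 ],
 "mean_spearman": [
  0.0014299507746366898,
  0.19401751331304093,
  0.3637489776694626,
  0.5073983177275811,
  0.6139296562752875,
  0.6935709942066278,
  0.75472210581679,
  0.798754472686568,
  0.8322562553722741,
  0.8585821629567988,
  0.8778132104953026,
  0.8917050401961585,
  0.9057197516730514,
  0.9136281731380265,
  0.9214086847993076,
  0.9266994260353183,
  0.9313486297590986,
  0.9332702023009672,
  0.9346818077144586,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736,
  0.9354987588487736
 ],
 "reference": {
  "mu": 50.0,
  "dispersion": 0.2,
  "n": 100,
  "reps": 1000
 }
}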