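06662a3d2c59c58a9d194da1b6884778f775ea8642598f0159ea0342fdad6ee9  cohort.ped
45f3fdc09ac0b0a228d1d1f71d8bf15fdaa7c30af976a1126a57f956b8d2efb8  variants.tsv
59631debe42c23af0e60764cb649593ad82c401dffec61f2883df7baf582869c  panel.txt
c91610fb6773906eb8fa86def5850aa297edb47689512375c4b77d25dbecce31  cnv_events.yaml
0ff8ac300cf91548c0cc0f391c4fb7457ddb6acb3aac0f77c7667c876d3cfdf9  evidence.yaml
baf002a52778b8827bc5561c22605252e110072e9b36631c6a4614dec3142f70  constants.yaml
2c6b55918bcfd9b83fe13216957f6e034ad0139f4ee93307dfd2167a4e91a4d8  str_profiles.tsv
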