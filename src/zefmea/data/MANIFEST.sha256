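46b9d6423572ee0c48dc0315a81771560f75ce86666c353cbb7712e7d16210fe  comparisons.csv
ce06aeee0b8e55761427434a23272ea16b61867f64211e6ad0abb3580d874615  failure_modes.csv
2dc9ff5f4cb03c4cf53dd0cf9f5baa536907c13f86dec3ff71744cde24efba72  initial_matrix.csv
96b9b86f6b500de0c74bf8d93975a2dffc9b3993313ebfad24f37c58a199227e  judgments.csv
9d27a80f8104977c9b3f90b0257ce020f73cf934fbd55476c92a18a524ffa359  normalized_printed.csv
bd6fbf1d60f53322e780a2b60c81e7b4a4742169e22f9b77f92d02ebdb182cd4  ranking_printed_z.csv
08fc09aaaed86ed10087623fc90c52dcec36c9570cb549f9aff495bac27d12c0  ranking_printed_ze.csv
1f37c90ebe73abd878c70662ec101d152fd52955cbc36d68b2f84879616ec6f5  scales.yaml
fd4e3dc01b3a90a53212f72b08b9a9687e728fabb8d25340be2d4c2e4f163085  votes.csv
35bb660e41dc39719d218c30c53fc632ecbb831bec621806d6cb21716cdfd76f  ze_bwm_weights.csv
595c9ea6cd9c06d23fefab49cb034180052147ed7fe5fc29d634014b315a175c  ze_matrix_printed.csv
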