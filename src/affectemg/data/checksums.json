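{
 "table3_all": "769efe1105e5a174625ded8858155bcf8d24a9a6bfc74a2ddccb48c3c4c468ac",
 "table4_senior": "a04c7b93b01bc3ca2e0f5aa2e79fbf9616f8693878217e682ea7a17ecf6d4882",
 "table4_young": "3cb2e80dfc4df09d1aeac397959f03540176013baf3f68a379d8bbbbd3ef53f6",
 "table5_female": "f5486e24bda3c9da9fe0e6fbdd043f04eae2479537c734e1208e595232270360",
 "table5_male": "29f10d0154b7cf76a57a3971ef0c32586a0327bdcdaf61d7b8a1e54a85f24bc4",
 "table6_corrugator": "5d6b29e659a8329c5a1cefce47cadf87e2ebc335c85e1575b26cf510e8fcff06",
 "table7_zygomaticus": "c7328e78c4404bb0c315dd384f538bc81884f198666020e37d067eaa7a711cca"
}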