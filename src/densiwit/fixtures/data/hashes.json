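{
 "H2.molden": "2c288719c429bca178d32ed4e76becb4d8161b721868b3ecd67ec12f5b655c82",
 "H2.rdm.json": "25e816df124800e5f4d8eb05b237809d05790bbaaf80d3c1426e49aa2dd9ae28",
 "LiH.molden": "adc2c16cfc82cfab6e0b94f0ace6b11c2ce6dae40c7c4f3dfb745b886fbba339",
 "LiH.rdm.json": "99852e2ab4b2ffd67d1ef5da279a0c6deeb442ee17d02d6d1b8cf86711cbc1f6",
 "Li2.molden": "5a58e6db81a0e563311929a18b60ef8e6610164d20ce075ca70050c7e3337828",
 "Li2.rdm.json": "ba78ce10ff9199e916e9ca9ceeb4503dabfea89b77512ed3d00830a5857873bd",
 "HCN.molden": "672d1dc6ba38dd99d0313e1b3bd2709691e40274882e1dff2b59885bd94dc627",
 "HCN.rdm.json": "ee44b8b189152aa3a7c9ff90455a4daffa89de125797b0196a4d5078e9d1ed00",
 "H2_witness.molden": "ce5a0e5240caf68760a91c7d92720d0a0097b509fdd796e0479a8bd8f7c6ede4",
 "H2_witness.rdm.json": "9249e6bd60ea731d86275354021886f867ed54a0db93569e7c82bb52dcdd6d1e"
}
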