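{
  "seed": 7654321,
  "sha256": {
    "bundle/cohort.txt": "68db616c4e07cf123a7f1e8c5427bddd9648c929b08679e7ae4932253f47c64e",
    "bundle/documents.jsonl": "64aea03bf8e759df7fda8dff774eed52290178fa6088b376b04e0b50e5f6c9bb",
    "bundle/hierarchy.tsv": "65c508eb9aefd93258356d5382ac62db756748e8f47312178c9a306bcb1e1614",
    "bundle/judgments.tsv": "c9454adfec8954bc8128e3a808bfe28e3c57c246bd3c8eaecc887d3d64601b8d",
    "bundle/lexicon.tsv": "173388e2e6c46c73f23dffcb279d1a9199f4c96485de00989b46babb9b6bbede",
    "bundle/reference.tsv": "6a8192c4ec8253a1617b3f9218351e9ea7baa088a286a3f2f1bd42138e867c10",
    "bundle/triggers.tsv": "9052af7a03db402c4e019dd39477d9d865997aa08dff661457c86d957ed04dea",
    "bundle/truth_mentions.tsv": "48b39e0e15a11220be3f981caa7e0607fd141e3f390000d438245fe33377f014",
    "bundle/truth_patients.tsv": "54187fdafcf85a9f3398db82c01332582ee8a917ebfb55db9acf0a314ec30219",
    "bundle/truth_summary.json": "774b7f3c3921a6b0790485cffa5410e940736ff1ac8ea26056b90f166384c125",
    "context_table.json": "9d49c87b39ea6f30aa30129a8efb589465d2be28860880e998c51755a01724c6",
    "mentions.tsv": "d3ac0f25891846014309e3ce4876494d362f4c87e45ee4c90b6efea5e09c965e",
    "rankings.tsv": "d76acd5022284761c3d34793411bdcb6e7fe26b8db2e1d31c75e31a3ac1647b6",
    "report.tsv": "53ea895da10d0be0ec72c240ad43994db4c041fb6bdf19ae738067f659e07f16"
  }
}
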