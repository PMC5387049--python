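{
  "_comment": "Splice-junction fixtures for the ATP7A intron 6 and LKB1 intron 2 worked examples. The donor/acceptor motif cores (guaagu.../...ag and auauccuu.../...ac) and the cryptic guaag sites at intron positions +5 and +50 of ATP7A intron 6 are as published; the remaining interior bases are SYNTHETIC filler, constructed so that no unintended donor motif occurs elsewhere in the sequence.",
  "atp7a_intron6": {
    "gene": "ATP7A",
    "intron_ordinal": 6,
    "donor_seq": "guaaguaaga",
    "acceptor_seq": "uucuuuucag",
    "sequence": "guaaguaagaaacaaucaucaaccaugaagaaacaucaaucacaaagaaguaagaaauacaucaaucaacaaacuuacaucaacaauacauucuuuucag",
    "wild_motif": "guaagu_ag",
    "mutations": {
      "IVS6+1G>A": {"mutant_motif": null, "note": "MD1: gu core destroyed; cryptic guaag sites at +5 and +50"},
      "IVS6+5G>A": {"mutant_motif": "guaa_ag", "note": "MD2: enriched only in S-S"},
      "IVS6+6T>A": {"mutant_motif": "guaag_ag", "note": "OHS: enriched in A3-S and R-R"}
    }
  },
  "lkb1_intron2": {
    "gene": "LKB1",
    "intron_ordinal": 2,
    "donor_seq": "auauccuuuc",
    "acceptor_seq": "uucucuuuac",
    "sequence": "auauccuuucaaacaucaacaaucaccaaacaucaaucaacaaacucaaauucucuuuac",
    "wild_motif": "auauccuu_ac",
    "mutations": {
      "IVS2+1A>G": {"mutant_motif": null, "note": "PJS: guauccuu_ac is absent from the paired table"}
    }
  }
}
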