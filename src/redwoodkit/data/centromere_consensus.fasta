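>centromere_consensus_148bp
AAAAAATGAAGGTTCGCGAAAGGCGATAGAAAATACGCGTACAGAATGCACAACTACAGT
GCAATCCACAATCGTAGTCACCAAAGTTGATCGATGGCCCACGAAAACTCAAACACGAGC
GGTTTCCTAAATGCGGCTATAACTCAAC
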