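# Cis-acting regulatory element catalog for promoter scanning.
# Consensus strings use IUPAC degeneracy codes and follow the motif
# definitions popularized by the PlantCARE collection; they are
# editable configuration, and users can load their own catalog.
#
# categories: core | stress | hormone | light | development
- {name: TATA-box,    consensus: TATAAA,     category: core}
- {name: CAAT-box,    consensus: CCAAT,      category: core}
- {name: A-box,       consensus: CCGTCC,     category: core}
- {name: ARE,         consensus: AAACCA,     category: stress}
- {name: MBS,         consensus: CAACTG,     category: stress}
- {name: MYB,         consensus: TAACCA,     category: stress}
- {name: LTR,         consensus: CCGAAA,     category: stress}
- {name: TC-rich,     consensus: ATTTTCTTCA, category: stress}
- {name: DRE,         consensus: RCCGAC,     category: stress}
- {name: ABRE,        consensus: ACGTG,      category: hormone}
- {name: TGACG-motif, consensus: TGACG,      category: hormone}
- {name: CGTCA-motif, consensus: CGTCA,      category: hormone}
- {name: TGA-element, consensus: AACGAC,     category: hormone}
- {name: TCA-element, consensus: CCATCTTTTT, category: hormone}
- {name: GARE-motif,  consensus: TCTGTTG,    category: hormone}
- {name: P-box,       consensus: CCTTTTG,    category: hormone}
- {name: TATC-box,    consensus: TATCCCA,    category: hormone}
- {name: AuxRR-core,  consensus: GGTCCAT,    category: hormone}
- {name: ERE,         consensus: ATTTCAAA,   category: hormone}
- {name: W-box,       consensus: TTGACC,     category: hormone}
- {name: G-box,       consensus: CACGTG,     category: light}
- {name: ACE,         consensus: GACACGTATG, category: light}
- {name: Box 4,       consensus: ATTAAT,     category: light}
- {name: GT1-motif,   consensus: GGTTAA,     category: light}
- {name: Sp1,         consensus: GGGCGG,     category: light}
- {name: TCT-motif,   consensus: TCTTAC,     category: light}
- {name: GATA-motif,  consensus: GATAGGA,    category: light}
- {name: I-box,       consensus: GATAAGGCC,  category: light}
- {name: AE-box,      consensus: AGAAACAA,   category: light}
- {name: Box II,      consensus: CCACGTGGC,  category: light}
- {name: TCCC-motif,  consensus: TCTCCCT,    category: light}
- {name: O2-site,     consensus: GATGAYRTGR, category: development}
- {name: CAT-box,     consensus: GCCACT,     category: development}
- {name: RY-element,  consensus: CATGCATG,   category: development}
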