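# Restriction enzymes for CAPS assays. recognition_site uses IUPAC codes;
# cut_offset counts bases from the 5' end of the site to the cut.
BanI:
  recognition_site: GGYRCC
  cut_offset: 1
ApaLI:
  recognition_site: GTGCAC
  cut_offset: 1
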