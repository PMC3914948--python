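# Example SSU rRNA domain color scheme (5', Central, 3' Major, 3' minor).
# Ranges are illustrative placeholders for an E. coli-sized 16S
# (1542 nt); exact domain boundaries are a curation choice and should be
# edited to match the structure at hand.
domains:
  - name: "5'"
    color: blue
    ranges: [[1, 560]]
  - name: "C"
    color: brown
    ranges: [[561, 920]]
  - name: "3'M"
    color: pink
    ranges: [[921, 1390]]
  - name: "3'm"
    color: green
    ranges: [[1391, 1542]]
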