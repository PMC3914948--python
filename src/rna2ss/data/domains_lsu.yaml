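# Example LSU rRNA domain color scheme (Domain 0, I-VI, 5.8S, 5S).
# Ranges are illustrative placeholders over a 23S/28S-sized index space
# with 5.8S and 5S concatenated after the large rRNA; exact domain
# boundaries are a curation choice and should be edited to match the
# structure at hand.
domains:
  - name: "Domain 0"
    color: orange
    ranges: [[1, 560]]
  - name: "I"
    color: purple
    ranges: [[561, 680]]
  - name: "II"
    color: blue
    ranges: [[681, 1270]]
  - name: "III"
    color: magenta
    ranges: [[1271, 1640]]
  - name: "IV"
    color: yellow
    ranges: [[1641, 2010]]
  - name: "V"
    color: pink
    ranges: [[2011, 2620]]
  - name: "VI"
    color: green
    ranges: [[2621, 2904]]
  - name: "5.8S"
    color: brown
    ranges: [[2905, 3060]]
  - name: "5S"
    color: lightgreen
    ranges: [[3061, 3180]]
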