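# Default region definitions for the trace amine receptor comparison.
#
# binding_site: the orthosteric pocket residues named in experimental
# agonist-bound structures (Ballesteros-Weinstein: D103 3.32, V184 45.52,
# F186 45.54, T194 5.42, F195 5.43, S198 5.46, F267 6.51, F268 6.52). The BW
# labels are precomputed constants, not derived here.
# The range regions are illustrative extracellular selections; real analyses
# should supply their own ranges for the structures at hand.
binding_site:
  chain: A
  residues: [103, 184, 186, 194, 195, 198, 267, 268]
tm_extracellular:
  chain: A
  ranges: [[95, 110], [190, 205], [260, 275]]
loops:
  chain: A
  ranges: [[175, 189]]
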