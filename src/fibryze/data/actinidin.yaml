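# Positional substrate-specificity definition for actinidin (EC 3.4.22.14),
# the papain-family cysteine protease of kiwifruit.
#
# Two independent evidence sources, each a set of allowed residues per
# Schechter-Berger position (P4..P1 N-terminal of the scissile bond,
# P1'..P4' C-terminal). An absent position is unconstrained. Under the
# default any_source combination a P1 position is a cleavage site when at
# least one source is fully satisfied.
name: actinidin
combination: any_source
sources:
  - label: kiwellin
    positions:
      P1: [T, H, R]
      P1': [T, S, G]
  - label: insulin
    positions:
      P4: [G, A, S, P, E, K, R, H]
      P3: [G, P, A, F, L, S, K, H]
      P2: [F, A, V, L, S, M, Y, D, E]
      P1: [G, A, F, Y, R, V, N, Q, E, K, H]
      P1': [G, V, L, Y, S, T, Q, D, E]
      P2': [P, F, A, V, H, G, M, T]
      P3': [G, L, F, P, V, D, E, K]
      P4': [P, A, Y, G, V, L, D, K]
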