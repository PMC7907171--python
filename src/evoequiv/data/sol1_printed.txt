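(!If[*s*, If[!(!nw&&If[se, !west, north]), north,
If[!(*n*||If[If[!west, ne, !If[west, se, nw]], nw, south&&!(*w*&&*n*)]||(west&&If[*w*, east, If[If[*s*, If[!west, !If[west, se, nw], *n*],
If[ne, south, east]], If[!*n*||east, north, (north&&north)||sw],
If[!If[north, *n*, If[west,
(!If[*s*, If[west, !If[ne, !sw, west], east],
If[ne, south, nw]]&&west&&south)&&If[se, !west, south], *n*]]&&south, sw, True]]])||se),
!If[south, se, nw], *n*]], If[If[*s*, west, If[se, south, If[!*n*||east, north,
!(!(east&&nw)&&south&&east)]]], south, east]]&&south&&*e*),
||south
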