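If[If[*e*, If[sw, west, se]&&south, !If[!ne&&*w*, ne||north,
If[!If[ne, east, *w*], *n*, east]&&east]]&&west, south, east]
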