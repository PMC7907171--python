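If[If[!If[*e*, If[If[*e*, nw, ne], *w*, north]||*s*, If[se, east, False]],
If[*w*, nw&&!south, *w*], *s*], west&&*n*, west]||(east&&!*w*)
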