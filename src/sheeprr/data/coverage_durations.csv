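phase,duration
sheep_in_scene,35:56:27
at_rest,29:38:23
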