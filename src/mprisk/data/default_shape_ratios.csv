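# Default length:width:height aspect-ratio bounds per microplastic shape.
# wl = width/length, hl = height/length; length is the longest dimension.
# Package-constructed defaults (see docs/methods.md): the fragment upper
# bounds coincide with the sphere, fibers are slender cylinders, films are
# thin sheets; upper bounds set so the maximum-ratio volume coefficients
# (fragment pi/6, fiber (pi/4)*wl_high^2, film wl_high*hl_high) are spaced
# consistently with observed shape-resolved risk ratios.
shape,wl_low,wl_high,hl_low,hl_high
fragment,0.1,1.0,0.1,1.0
sphere,1.0,1.0,1.0,1.0
fiber,0.01,0.37,0.01,0.37
film,0.5,1.0,0.005,0.014
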