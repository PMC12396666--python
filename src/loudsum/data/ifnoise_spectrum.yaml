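# Third-octave band spectrum shape of the binaural female speech-shaped
# noise (IFnoise) test signal — a versioned fixture with an LTASS-like
# female-speech shape.  `shape_db` holds relative band levels; at run time
# the shape is offset so that the power sum equals the requested overall
# broadband level, and the same shape is used at every input level.
version: 1
band_center_hz: [125, 160, 200, 250, 315, 400, 500, 630, 800, 1000,
                 1250, 1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000]
shape_db: [46.0, 50.0, 53.5, 56.5, 58.5, 59.5, 59.0, 57.5, 55.5, 53.5,
           52.0, 50.5, 49.0, 47.5, 46.0, 44.0, 41.5, 39.0, 36.0]
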