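{
  "krumhansl_kessler": {
    "provenance": "Krumhansl & Kessler (1982) probe-tone key profiles, as tabulated in Krumhansl, Cognitive Foundations of Musical Pitch (1990), Table 2.1",
    "major": [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88],
    "minor": [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
  },
  "temperley": {
    "provenance": "Temperley (1999), 'What's Key for Key? The Krumhansl-Schmuckler Key-Finding Algorithm Reconsidered', Music Perception 17(1), modified key profiles",
    "major": [5.0, 2.0, 3.5, 2.0, 4.5, 4.0, 2.0, 4.5, 2.0, 3.5, 1.5, 4.0],
    "minor": [5.0, 2.0, 3.5, 4.5, 2.0, 4.0, 2.0, 4.5, 3.5, 2.0, 1.5, 4.0]
  }
}
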