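# Default Gleason-extraction lexicon and classifier settings.
# This is a reconstruction of a clinically standard vocabulary; extend or
# override it by passing your own config file to the CLI / load_lexicon.
version: "default-1"

# Context-window radii (characters, centered on the mention anchor) for
# specimen classification of clinical-note mentions. The search broadens
# through the list; null means "the whole note".
windows: [150, 500, null]

terms:
  # --- Gleason mention anchors -------------------------------------------
  - {surface: "Gleason", category: gleason_anchor, tier: 1}
  - {surface: "GS", category: gleason_anchor, tier: 1}

  # --- prostate surgery cues ---------------------------------------------
  - {surface: "prostatectomy", category: surgery_cue, tier: 1}
  - {surface: "radical prostatectomy", category: surgery_cue, tier: 1}
  - {surface: "retropubic radical prostatectomy", category: surgery_cue, tier: 1}
  - {surface: "RRP", category: surgery_cue, tier: 1}
  - {surface: "RALP", category: surgery_cue, tier: 1}
  - {surface: "pathologic stage", category: surgery_cue, tier: 2}
  - {surface: "prostate surgery", category: surgery_cue, tier: 2}

  # --- prostate biopsy cues ----------------------------------------------
  - {surface: "PNBx", category: biopsy_cue, tier: 1}
  - {surface: "prostate needle biopsy", category: biopsy_cue, tier: 1}
  - {surface: "needle biopsy", category: biopsy_cue, tier: 1}
  - {surface: "core biopsy", category: biopsy_cue, tier: 1}
  - {surface: "prostate biopsy", category: biopsy_cue, tier: 1}
  - {surface: "biopsy", category: biopsy_cue, tier: 2}
  - {surface: "Bx", category: biopsy_cue, tier: 2}
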