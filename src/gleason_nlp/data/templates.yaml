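# Template bank for the synthetic note generator. Placeholders:
#   {p} {s} {t}  score components     {cue}  specimen cue surface
#   {date}       ISO date
# The combined clinical template uses {bp}/{bs}/{bt} (biopsy) and
# {sp}/{ss}/{st} (surgery) with {bcue}/{scue} cues. Add dialects freely;
# every score-bearing template must contain a Gleason anchor and a cue.

cues_biopsy: ["PNBx", "prostate needle biopsy", "core biopsy"]
cues_surgery: ["RRP", "RALP", "radical prostatectomy", "prostatectomy"]

clinical_complete:
  - "Prostate cancer s/p {cue} {date}. Gleason {p}+{s}={t}. Plan discussed."
  - "Hx: {cue} {date} showed Gleason score {p}+{s}={t}."
  - "{cue} pathology notable for GS {t} ({p}+{s})."
  - "Per {cue} report dated {date}, Gleason {p}+{s} disease."
  - "Assessment: prostate adenocarcinoma, Gleason {p}+{s}={t} on {cue} {date}."
  - "Reviewed outside {cue} records: Gleason score {t} ({p}+{s})."

clinical_total_only:
  - "Known Gleason {t} prostate cancer, status post {cue}."
  - "Follow-up for GS {t} disease ({cue} {date})."

clinical_combined:
  - "{bcue} {date}: Gleason {bp}+{bs}={bt}. Subsequently s/p {scue} with Gleason {sp}+{ss}={st}."

clinical_distractor:
  - "Patient seen in follow-up today. PSA stable. No new complaints."
  - "Telephone encounter: medication refill requested and approved."
  - "Review of systems negative. Continue current management."
  - "Discussed diet and exercise. Return to clinic in 6 months."
  - "Urology follow-up. Voiding symptoms improved on tamsulosin."

pathology_biopsy:
  - "PROSTATE, NEEDLE BIOPSY ({date}): Adenocarcinoma, Gleason score {p}+{s}={t}, involving 3 of 12 cores."
  - "FINAL DIAGNOSIS: Prostate, core biopsy ({date}): adenocarcinoma, GS {t} ({p}+{s})."

pathology_surgery:
  - "PROSTATE, RADICAL PROSTATECTOMY ({date}): Prostatic adenocarcinoma, Gleason {p}+{s}={t}; margins negative."
  - "FINAL DIAGNOSIS: Prostate, prostatectomy specimen ({date}): adenocarcinoma, Gleason score {t} ({p}+{s}). Pathologic stage pT2."

pathology_distractor:
  - "SKIN, LEFT FOREARM, SHAVE: Basal cell carcinoma, margins uninvolved."
  - "GALLBLADDER, CHOLECYSTECTOMY: Chronic cholecystitis with cholelithiasis."

conflict_clinical:
  - "Outside records review ({date}): {cue} reportedly Gleason {p}+{s}={t}."
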