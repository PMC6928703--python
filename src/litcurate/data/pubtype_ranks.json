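{
  "table": [
    {"type": "systematic reviews", "rank": 1, "grade": "H"},
    {"type": "meta-analysis of rcts", "rank": 1, "grade": "H"},
    {"type": "rcts", "rank": 3, "grade": "H"},
    {"type": "meta-analysis of cts", "rank": 4, "grade": "M"},
    {"type": "systematic review of cts", "rank": 5, "grade": "M"},
    {"type": "ct", "rank": 6, "grade": "M"},
    {"type": "cohort study/case-control study/report", "rank": 7, "grade": "M"},
    {"type": "guidelines", "rank": 8, "grade": "L"},
    {"type": "opinion", "rank": 9, "grade": "L"},
    {"type": "observational study", "rank": 10, "grade": "L"},
    {"type": "any other publication type", "rank": 11, "grade": "L"}
  ],
  "aliases": {
    "systematic review": "systematic reviews",
    "meta-analysis": "meta-analysis of rcts",
    "meta analysis": "meta-analysis of rcts",
    "randomized controlled trial": "rcts",
    "controlled clinical trial": "ct",
    "clinical trial": "ct",
    "cohort study": "cohort study/case-control study/report",
    "cohort studies": "cohort study/case-control study/report",
    "case-control study": "cohort study/case-control study/report",
    "case control study": "cohort study/case-control study/report",
    "case reports": "cohort study/case-control study/report",
    "case report": "cohort study/case-control study/report",
    "practice guideline": "guidelines",
    "guideline": "guidelines",
    "editorial": "opinion",
    "comment": "opinion",
    "letter": "opinion"
  }
}
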