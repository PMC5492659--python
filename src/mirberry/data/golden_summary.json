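{
  "abundance_spectrum": {
    "1": [
      202,
      86.6953
    ],
    "1001-10000": [
      0,
      0.0
    ],
    "101-1000": [
      0,
      0.0
    ],
    "11-100": [
      0,
      0.0
    ],
    "2": [
      7,
      3.00429
    ],
    "3-10": [
      24,
      10.3004
    ],
    ">10000": [
      0,
      0.0
    ]
  },
  "accounting": {
    "adapter3_null": 12,
    "clean": 331,
    "contaminant5": 7,
    "high_quality": 383,
    "insert_null": 11,
    "low_quality": 17,
    "polya": 18,
    "raw": 400,
    "too_long": 2,
    "too_short": 2
  },
  "accounting_percent": {
    "adapter3_null": 3.0,
    "clean": 82.75,
    "contaminant5": 1.75,
    "high_quality": 95.75,
    "insert_null": 2.75,
    "low_quality": 4.25,
    "polya": 4.5,
    "too_long": 0.5,
    "too_short": 0.5
  },
  "conserved": {
    "families": 6,
    "first_base_percent": {
      "A": 11.3208,
      "C": 18.8679,
      "G": 45.283,
      "U": 24.5283
    },
    "member_read_pearson_p": 0.000245379,
    "member_read_pearson_r": 0.987183,
    "overall_base_percent": {
      "A": 25.0906,
      "C": 25.4529,
      "G": 27.7174,
      "U": 21.7391
    },
    "reads": 139,
    "unique_tags": 53
  },
  "enrichment": {
    "enriched": [
      "GO:0999999"
    ],
    "terms_tested": 20
  },
  "novel": {
    "accepted": 0,
    "candidates": 0,
    "mfei_max": null,
    "mfei_mean": null,
    "mfei_min": null,
    "with_mipep_orf": 0
  },
  "size_distribution_reads": {
    "18": 1.20846,
    "19": 1.81269,
    "20": 20.2417,
    "21": 29.003,
    "22": 14.8036,
    "23": 5.74018,
    "24": 23.8671,
    "25": 2.41692,
    "26": 0.302115,
    "29": 0.302115,
    "30": 0.302115
  },
  "tag_categories": {
    "cDNA": 115,
    "conserved-miRNA": 53,
    "other": 0,
    "rRNA": 31,
    "snRNA": 0,
    "snoRNA": 0,
    "tRNA": 15,
    "unclassified": 19
  },
  "tag_category_percent": {
    "cDNA": 49.356,
    "conserved-miRNA": 22.747,
    "other": 0.0,
    "rRNA": 13.305,
    "snRNA": 0.0,
    "snoRNA": 0.0,
    "tRNA": 6.438,
    "unclassified": 8.155
  },
  "targets": {
    "cleavage": 9,
    "hits": 15,
    "target_genes": 15,
    "translational_repression": 6
  },
  "unique_tags": 233
}
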