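{
  "description": "Reported held-out confusion matrices (rows = actual, cols = predicted; class order pass, questionable, fail) for four slice-network variants of the hierarchical dMRI IQA framework, at volume and subject level, plus the cohort geometry of the originating pediatric study.",
  "confusion_matrices": {
    "DSR": {
      "volume": [[1254, 892, 2], [132, 1000, 38], [10, 62, 234]],
      "subject": [[4, 6, 0], [1, 9, 0], [0, 1, 3]]
    },
    "DSR+NLR": {
      "volume": [[1569, 579, 0], [63, 1102, 5], [18, 66, 222]],
      "subject": [[7, 3, 0], [1, 9, 0], [0, 1, 3]]
    },
    "NLDR+NLR": {
      "volume": [[1952, 196, 0], [33, 1135, 2], [0, 15, 291]],
      "subject": [[9, 1, 0], [0, 10, 0], [0, 0, 4]]
    },
    "DSR+NLDR+NLR": {
      "volume": [[2134, 14, 0], [23, 1147, 0], [0, 0, 306]],
      "subject": [[10, 0, 0], [0, 10, 0], [0, 0, 4]]
    }
  },
  "cohort_geometry": {
    "volumes_per_subject": 151,
    "slices_per_volume": 60,
    "labeled_training_volumes": 150,
    "training_volume_class_counts": [85, 25, 40],
    "unlabeled_subjects": 78,
    "test_subjects": 24
  }
}
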