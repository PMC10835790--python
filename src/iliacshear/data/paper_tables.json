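{
  "description": "Per-patient clinical/computational metric values and demographics for the 4-case (Subject) / 4-control iliac vein compression cohort, transcribed from the source study's printed tables, plus the printed summary statistics used as regression targets.",
  "demographics": {
    "age_years": {
      "Subject": [25, 41, 52, 47],
      "Control": [85, 62, 62, 61],
      "printed": {"subject_avg": "41.3", "subject_std": "11.7", "control_avg": "67.5", "control_std": "11.7", "p": "0.019"}
    },
    "height_m": {
      "Subject": [1.59, 1.73, 1.83, 1.65],
      "Control": [1.78, 1.65, 1.65, 1.63],
      "printed": {"subject_avg": "1.7", "subject_std": "0.1", "control_avg": "1.7", "control_std": "0.1", "p": "0.731"}
    },
    "weight_kg": {
      "Subject": [56.3, 104.2, 73.0, 81.6],
      "Control": [93.2, 112.0, 80.4, 111.4],
      "printed": {"subject_avg": "78.8", "subject_std": "19.9", "control_avg": "99.3", "control_std": "15.3", "p": "0.154"}
    },
    "bmi": {
      "Subject": [22.3, 34.9, 21.8, 29.9],
      "Control": [29.4, 41.1, 29.5, 42.1],
      "printed": {"subject_avg": "27.2", "subject_std": "6.3", "control_avg": "35.5", "control_std": "7.0", "p": "0.129"}
    },
    "respiratory_length_s": {
      "Subject": [3.0, 3.0, 3.75, 3.2],
      "Control": [3.0, 3.75, 3.5, 3.0],
      "printed": {"subject_avg": "3.2", "subject_std": "0.4", "control_avg": "3.3", "control_std": "0.4", "p": "0.781"}
    }
  },
  "metrics": {
    "LCIV": {
      "area_mm2": {
        "Subject": [76.2, 30.6, 73.4, 110.3],
        "Control": [142.1, 131.5, 126.0, 127.8],
        "printed": {"subject_avg": "72.6", "subject_std": "32.7", "control_avg": "131.8", "control_std": "7.2", "p": "0.01218"}
      },
      "flow_l_min": {
        "Subject": [1.154, 0.308, 0.469, 0.608],
        "Control": [1.184, 1.010, 0.694, 0.767],
        "printed": {"subject_avg": "0.635", "subject_std": "0.367", "control_avg": "0.914", "control_std": "0.225", "p": "0.24318"}
      },
      "mean_shear_1_s": {
        "Subject": [571, 480, 688, 462],
        "Control": [131, 58, 53, 59],
        "printed": {"subject_avg": "550", "subject_std": "103", "control_avg": "75", "control_std": "37", "p": "0.00013"}
      },
      "q1_shear_1_s": {
        "Subject": [236, 267, 348, 130],
        "Control": [43, 22, 18, 23],
        "printed": {"subject_avg": "245", "subject_std": "90", "control_avg": "27", "control_std": "11", "p": "0.00296"}
      },
      "q3_shear_1_s": {
        "Subject": [862, 672, 986, 720],
        "Control": [202, 80, 81, 92],
        "printed": {"subject_avg": "810", "subject_std": "142", "control_avg": "114", "control_std": "59", "p": "0.00010"}
      },
      "mean_peak_shear_1_s": {
        "Subject": [1688, 1191, 2257, 1475],
        "Control": [503, 187, 159, 175],
        "printed": {"subject_avg": "1653", "subject_std": "451", "control_avg": "256", "control_std": "165", "p": "0.00114"}
      }
    },
    "RCIV": {
      "area_mm2": {
        "Subject": [120.4, 172.3, 113.8, 378.7],
        "Control": [105.6, 140.9, 165.3, 142.3],
        "printed": {"subject_avg": "196.3", "subject_std": "124.4", "control_avg": "138.5", "control_std": "24.6", "p": "0.39748"}
      },
      "flow_l_min": {
        "Subject": [0.900, 1.609, 1.352, 2.086],
        "Control": [0.578, 0.680, 1.238, 0.767],
        "printed": {"subject_avg": "1.487", "subject_std": "0.495", "control_avg": "0.816", "control_std": "0.292", "p": "0.05836"}
      },
      "mean_shear_1_s": {
        "Subject": [89, 103, 183, 78],
        "Control": [59, 39, 64, 55],
        "printed": {"subject_avg": "113", "subject_std": "48", "control_avg": "54", "control_std": "11", "p": "0.05209"}
      },
      "q1_shear_1_s": {
        "Subject": [35, 41, 51, 28],
        "Control": [22, 18, 26, 33],
        "printed": {"subject_avg": "39", "subject_std": "10", "control_avg": "25", "control_std": "6", "p": "0.05312"}
      },
      "q3_shear_1_s": {
        "Subject": [132, 146, 249, 85],
        "Control": [69, 58, 92, 69],
        "printed": {"subject_avg": "153", "subject_std": "69", "control_avg": "72", "control_std": "14", "p": "0.06149"}
      },
      "mean_peak_shear_1_s": {
        "Subject": [254, 385, 923, 616],
        "Control": [316, 100, 260, 174],
        "printed": {"subject_avg": "545", "subject_std": "293", "control_avg": "213", "control_std": "95", "p": "0.07478"}
      }
    },
    "ratio": {
      "lciv_rciv_shear_ratio": {
        "Subject": [7.21, 5.59, 6.02, 7.43],
        "Control": [2.21, 1.58, 0.84, 1.09],
        "printed": {"subject_avg": "6.56", "subject_std": "0.90", "control_avg": "1.43", "control_std": "0.60", "p": "0.00008"}
      }
    }
  },
  "paired_p_printed": {
    "Subject": {"area_mm2": "0.104", "flow_l_min": "0.117", "mean_shear_1_s": "0.0009"},
    "Control": {"area_mm2": "0.700", "flow_l_min": "0.718", "mean_shear_1_s": "0.329"}
  },
  "headline_printed": {
    "ratio_of_ratios": "4.6",
    "subject_lciv_mean_peak_avg_1_s": "1653",
    "control_lciv_mean_peak_avg_1_s": "256"
  }
}
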