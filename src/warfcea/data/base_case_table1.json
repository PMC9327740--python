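{
  "arm_intervention": {
    "initial_within": {"base": 0.9942, "low": 0.8948, "high": 1.0937},
    "initial_below": {"base": 0.0029, "low": 0.0026, "high": 0.0032},
    "initial_above": {"base": 0.0029, "low": 0.0026, "high": 0.0032},
    "p_within_to_below": {"base": 0.0225, "low": 0.0203, "high": 0.0248},
    "p_within_to_above": {"base": 0.0191, "low": 0.0172, "high": 0.0210},
    "p_below_to_within": {"base": 0.4263, "low": 0.3837, "high": 0.4689},
    "p_above_to_within": {"base": 0.5712, "low": 0.5141, "high": 0.6283}
  },
  "arm_control": {
    "initial_within": {"base": 0.9855, "low": 0.8869, "high": 1.0840},
    "initial_below": {"base": 0.0058, "low": 0.0052, "high": 0.0063},
    "initial_above": {"base": 0.0087, "low": 0.0079, "high": 0.0096},
    "p_within_to_below": {"base": 0.0741, "low": 0.0667, "high": 0.0815},
    "p_within_to_above": {"base": 0.0383, "low": 0.0345, "high": 0.0421},
    "p_below_to_within": {"base": 0.1589, "low": 0.1430, "high": 0.1748},
    "p_above_to_within": {"base": 0.291, "low": 0.2619, "high": 0.3201}
  },
  "events": {
    "p_above_to_bleeding": {"base": 0.0115, "low": 0.0104, "high": 0.0127},
    "p_below_to_te": {"base": 0.0023, "low": 0.0021, "high": 0.0025},
    "te_to_bleeding": {"base": 0.00228, "low": 0.00205, "high": 0.00251},
    "te_to_reoperation": {"base": 0.00033, "low": 0.00030, "high": 0.00037},
    "te_to_death": {"base": 0.00374, "low": 0.00337, "high": 0.00412},
    "te_to_te": {"base": 0.08825, "low": 0.07942, "high": 0.09707},
    "bleeding_to_te": {"base": 0.00059, "low": 0.00053, "high": 0.00064},
    "bleeding_to_reoperation": {"base": 0.00033, "low": 0.00030, "high": 0.00037},
    "bleeding_to_death": {"base": 0.01078, "low": 0.00971, "high": 0.01186},
    "bleeding_to_bleeding": {"base": 0.02049, "low": 0.01844, "high": 0.02254},
    "reop_to_te": {"base": 0.00014, "low": 0.00012, "high": 0.00015},
    "reop_to_bleeding": {"base": 0.00028, "low": 0.00025, "high": 0.00031},
    "reop_to_death": {"base": 0.00035, "low": 0.00031, "high": 0.00038},
    "reop_to_reop": {"base": 0.00033, "low": 0.00030, "high": 0.00037},
    "recovery_to_te": {"base": 0.00059, "low": 0.00025, "high": 0.00109},
    "recovery_to_bleeding": {"base": 0.00228, "low": 0.00109, "high": 0.00532},
    "recovery_to_reoperation": {"base": 0.00033, "low": 0.00017, "high": 0.00075},
    "recovery_to_death": {"base": 0.00147, "low": 0.00131, "high": 0.00163},
    "rr_death_major_te": {"base": 2.25, "low": 1.75, "high": 2.75},
    "rr_death_major_bleeding": {"base": 1.5, "low": 1.0, "high": 2.0}
  },
  "utilities": {
    "u_within_range": {"base": 0.987, "low": 0.967, "high": 0.998},
    "u_bleeding": {"base": 0.54, "low": 0.44, "high": 0.74},
    "u_te": {"base": 0.45, "low": 0.35, "high": 0.55},
    "u_reoperation": {"base": 0.45, "low": 0.35, "high": 0.75},
    "u_recovery": {"base": 0.668, "low": 0.61, "high": 0.76},
    "u_death": 0.0
  },
  "costs": {
    "c_bleeding": {"base": 2777.78, "low": 2500.00, "high": 3055.56},
    "c_te": {"base": 2314.81, "low": 2083.33, "high": 2546.30},
    "c_reoperation": {"base": 16203.70, "low": 14583.33, "high": 17824.07}
  },
  "discount_horizon": {
    "annual_discount_cost": {"base": 0.035, "low": 0.02, "high": 0.06},
    "annual_discount_qaly": {"base": 0.035, "low": 0.02, "high": 0.06},
    "cycle_length_months": 1,
    "horizon_cycles": 480,
    "half_cycle_correction": true
  },
  "inr_range_low": 2.5,
  "inr_range_high": 3.5
}
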