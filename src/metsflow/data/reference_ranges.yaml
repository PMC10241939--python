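# Clinical reference limits for the 18 continuous exam indicators.
#
# For the five MetS-component indicators (WC, SBP, DBP, TG, HDL-C, FGLU) the
# normal limit IS the diagnostic threshold of the Chinese 2017 T2DM guideline
# and abnormality is inclusive (>= / <=). For the remaining indicators the
# guideline prints no limit; the values below are standard Chinese adult
# reference ranges and are meant to be overridden from a site-specific file.
#
# plausible_low/plausible_high are physician plausibility bounds used for
# outlier removal (values outside become missing); they are deliberately much
# wider than the normal range and are NOT taken from any publication.
#
# risk_direction: "high" = values above the upper limit are the risk state;
# "low" = values below the lower limit are the risk state (HDL-C only).
indicators:
  - name: WC
    units: cm
    risk_direction: high
    inclusive: true
    sex_specific: {male: {upper: 90.0}, female: {upper: 85.0}}
    plausible_low: 40.0
    plausible_high: 200.0
  - name: WHR
    units: ratio
    risk_direction: high
    inclusive: false
    sex_specific: {male: {upper: 0.90}, female: {upper: 0.85}}
    plausible_low: 0.4
    plausible_high: 1.5
  - name: SBP
    units: mmHg
    risk_direction: high
    inclusive: true
    upper: 130.0
    plausible_low: 60.0
    plausible_high: 300.0
  - name: DBP
    units: mmHg
    risk_direction: high
    inclusive: true
    upper: 85.0
    plausible_low: 30.0
    plausible_high: 200.0
  - name: TG
    units: mmol/L
    risk_direction: high
    inclusive: true
    upper: 1.70
    plausible_low: 0.05
    plausible_high: 30.0
  - name: HDL-C
    units: mmol/L
    risk_direction: low
    inclusive: true
    lower: 1.04
    plausible_low: 0.05
    plausible_high: 5.0
  - name: LDL-C
    units: mmol/L
    risk_direction: high
    inclusive: false
    upper: 3.37
    plausible_low: 0.1
    plausible_high: 15.0
  - name: BMI
    units: kg/m^2
    risk_direction: high
    inclusive: false
    upper: 24.0
    plausible_low: 10.0
    plausible_high: 60.0
  - name: TC
    units: mmol/L
    risk_direction: high
    inclusive: false
    upper: 5.18
    plausible_low: 1.0
    plausible_high: 20.0
  - name: FGLU
    units: mmol/L
    risk_direction: high
    inclusive: true
    upper: 6.1
    plausible_low: 1.0
    plausible_high: 30.0
  - name: UA
    units: umol/L
    risk_direction: high
    inclusive: false
    sex_specific: {male: {upper: 420.0}, female: {upper: 360.0}}
    plausible_low: 50.0
    plausible_high: 1500.0
  - name: ALT
    units: U/L
    risk_direction: high
    inclusive: false
    upper: 40.0
    plausible_low: 1.0
    plausible_high: 1000.0
  - name: AST
    units: U/L
    risk_direction: high
    inclusive: false
    upper: 40.0
    plausible_low: 1.0
    plausible_high: 1000.0
  - name: HGB
    units: g/L
    risk_direction: high
    inclusive: false
    sex_specific: {male: {lower: 130.0, upper: 175.0}, female: {lower: 115.0, upper: 155.0}}
    plausible_low: 30.0
    plausible_high: 250.0
  - name: RBC
    units: 10^12/L
    risk_direction: high
    inclusive: false
    sex_specific: {male: {upper: 5.8}, female: {upper: 5.1}}
    plausible_low: 1.0
    plausible_high: 10.0
  - name: WBC
    units: 10^9/L
    risk_direction: high
    inclusive: false
    upper: 9.5
    plausible_low: 0.5
    plausible_high: 100.0
  - name: PLT
    units: 10^9/L
    risk_direction: high
    inclusive: false
    upper: 350.0
    plausible_low: 10.0
    plausible_high: 2000.0
  - name: CR
    units: umol/L
    risk_direction: high
    inclusive: false
    sex_specific: {male: {upper: 104.0}, female: {upper: 84.0}}
    plausible_low: 10.0
    plausible_high: 2000.0
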