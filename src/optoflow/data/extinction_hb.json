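{
  "description": "Molar decadic extinction coefficients of hemoglobin in water, units cm^-1 / (mol/L), from the Gratzer/Kollias compilation distributed by S. Prahl (Oregon Medical Laser Center) and shipped with common open fNIRS toolboxes.",
  "units": "cm^-1 M^-1 (decadic, base-10)",
  "version": 1,
  "coefficients": {
    "690": {"hbo": 276.0, "hbr": 2051.96},
    "760": {"hbo": 586.0, "hbr": 1548.52},
    "830": {"hbo": 974.0, "hbr": 693.04},
    "850": {"hbo": 1058.0, "hbr": 691.32}
  }
}
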