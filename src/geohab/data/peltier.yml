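# Weathering-regime regions in (mean annual temperature degC, annual
# precipitation mm) space, after Peltier's morphogenetic scheme. This is an
# editable rectangular digitization of the classical diagram, not a tracing
# of the original figure: rectangles partition the envelope T in [-30, 35),
# P in [0, 2500); lower edges closed, upper edges open unless *_closed.
envelope: {t_min: -30, t_max: 35, p_min: 0, p_max: 2500}
regions:
  - {label: strong_mechanical, t_min: -30, t_max: 0, p_min: 1000, p_max: 2500,
     p_max_closed: true}
  - {label: moderate_mechanical, t_min: -30, t_max: 0, p_min: 400, p_max: 1000}
  - {label: minimal_weathering, t_min: -30, t_max: 0, p_min: 0, p_max: 400}
  - {label: moderate_chemical_frost, t_min: 0, t_max: 10, p_min: 400,
     p_max: 2500, p_max_closed: true}
  - {label: slight_weathering, t_min: 0, t_max: 10, p_min: 0, p_max: 400}
  - {label: strong_chemical, t_min: 10, t_max: 35, t_max_closed: true,
     p_min: 1200, p_max: 2500, p_max_closed: true}
  - {label: moderate_chemical, t_min: 10, t_max: 35, t_max_closed: true,
     p_min: 400, p_max: 1200}
  - {label: slight_weathering, t_min: 10, t_max: 35, t_max_closed: true,
     p_min: 0, p_max: 400}
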