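# Four-class synthetic study; burst amplitude grows with the age class.
profiles:
  - {age_class: 0, n_films: 2, screenings_per_film: [8, 12],
     event_rate_per_h: 8, event_amplitude: 200, under12_fraction: 0.4}
  - {age_class: 6, n_films: 3, screenings_per_film: [8, 12],
     event_rate_per_h: 8, event_amplitude: 1000, under12_fraction: 0.2}
  - {age_class: 12, n_films: 2, screenings_per_film: [8, 12],
     event_rate_per_h: 10, event_amplitude: 5000}
  - {age_class: 16, n_films: 2, screenings_per_film: [8, 12],
     event_rate_per_h: 12, event_amplitude: 25000}
compounds:
  - {compound_id: m69.0699, noise_sigma: 0.05, inflow: 0.1, exit_spike: true}
  - {compound_id: CO2, unit: ppm, scale: 700, inflow: 400, noise_sigma: 2.0}
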