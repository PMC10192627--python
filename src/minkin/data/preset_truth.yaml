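# Built-in truth maps for the synthetic respirometry generator.
#
# "paper": truth kinetic constants for a published 5-soil phenanthrene
# slurry bioremediation study (treatments: A untreated control, B nutrient
# solution, C nutrients + HPBCD, D nutrients + degrader strain, E all
# three combined).  Amplitude m_max defaults to 100% of applied; observed
# plateaus of regenerated curves follow from the kinetics, they are not
# targets.
#
# "abiotic": sterile (HgCl2-poisoned) controls — zero rate in every soil,
# i.e. flat 0% curves.
paper:
  soils: [PLD, LL, ALC, CR, R]
  treatments: [A, B, C, D, E]
  truth:
    - {soil: PLD, treatment: A, model: SFO, k1: 2.1e-4}
    - {soil: PLD, treatment: B, model: FOMC, alpha: 0.14, beta: 0.36}
    - {soil: PLD, treatment: C, model: FOMC, alpha: 0.067, beta: 0.077}
    - {soil: PLD, treatment: D, model: FOMC, alpha: 0.17, beta: 0.59}
    - {soil: PLD, treatment: E, model: FOMC, alpha: 0.10, beta: 0.36}
    - {soil: LL, treatment: A, model: SFO, k1: 1.3e-4}
    - {soil: LL, treatment: B, model: HS, k1: 1.8e-2, k2: 1.7e-4, tb: 9.6}
    - {soil: LL, treatment: C, model: HS, k1: 1.4e-2, k2: 7.2e-4, tb: 12.3}
    - {soil: LL, treatment: D, model: HS, k1: 2.7e-2, k2: 7.3e-4, tb: 12.2}
    - {soil: LL, treatment: E, model: HS, k1: 2.4e-2, k2: 5.1e-4, tb: 16.1}
    - {soil: ALC, treatment: A, model: SFO, k1: 1.2e-3}
    - {soil: ALC, treatment: B, model: SFO, k1: 3.0e-4}
    - {soil: ALC, treatment: C, model: FOMC, alpha: 0.3, beta: 8.4}
    - {soil: ALC, treatment: D, model: FOMC, alpha: 0.3, beta: 4.9}
    - {soil: ALC, treatment: E, model: FOMC, alpha: 1.0, beta: 40.15}
    - {soil: CR, treatment: A, model: SFO, k1: 1.0e-3}
    - {soil: CR, treatment: B, model: SFO, k1: 1.2e-3}
    - {soil: CR, treatment: C, model: FOMC, alpha: 2.0, beta: 64.4}
    - {soil: CR, treatment: D, model: FOMC, alpha: 0.4, beta: 3.5}
    - {soil: CR, treatment: E, model: FOMC, alpha: 0.7, beta: 13.2}
    - {soil: R, treatment: A, model: SFO, k1: 1.3e-4}
    - {soil: R, treatment: B, model: HS, k1: 3.9e-3, k2: 4.4e-4, tb: 13.9}
    - {soil: R, treatment: C, model: HS, k1: 5.7e-2, k2: 1.7e-3, tb: 14.2}
    - {soil: R, treatment: D, model: HS, k1: 3.6e-2, k2: 4.9e-4, tb: 9.8}
    - {soil: R, treatment: E, model: HS, k1: 3.2e-2, k2: 5.6e-4, tb: 9.7}
abiotic:
  soils: [PLD, LL, ALC, CR, R]
  treatments: [A]
  # sterile flasks evolve no 14CO2: no signal and no counting noise
  noise_sd: 0.0
  truth:
    - {soil: PLD, treatment: A, model: SFO, k1: 0.0}
    - {soil: LL, treatment: A, model: SFO, k1: 0.0}
    - {soil: ALC, treatment: A, model: SFO, k1: 0.0}
    - {soil: CR, treatment: A, model: SFO, k1: 0.0}
    - {soil: R, treatment: A, model: SFO, k1: 0.0}
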