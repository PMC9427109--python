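"""Canonical desk-scale simulation scenarios.

These presets size the forward simulator so that each downstream stage has
measurable signal within seconds per replicate.  They are used by the test
suite, the acceptance report and the CLI defaults.

Notes on sizing (see also the per-scenario docstrings):

* The rearranged class holds ~25% of chromosomes, so its desk-scale
  effective size is tiny; scenarios that need localized haplotype signal
  therefore run few generations over a standing-variation-rich start
  (``init_theta_scale``) rather than many generations at mutation-drift
  equilibrium.
* Sweep localization requires recombination within reach of the sweep
  site; the sweep scenario allows partial heterokaryotype recombination
  (``c=0.5``) and places the swept locus near the rearrangement boundary,
  where arrangement-restricted selection is effective.
"""

from __future__ import annotations

from .simulate import BalancedSpec, SimConfig, SweepSpec

#: region used by the balancing-selection scenario (0-based half-open)
NFDS_REGION = (600_000, 650_000)

#: sweep site of the sweep scenario (1-based)
SWEEP_POSITION = 200_000


def neutral_scenario(seed: int) -> SimConfig:
    """Fully neutral balanced polymorphism: calibration and phasing tests.

    600 kb contig with a 400 kb rearrangement, full recombination
    suppression in heterokaryotypes, 500 seeded fixed differences, run for
    250 generations from near-equilibrium standing variation.
    """
    return SimConfig(
        n_individuals=200,
        contig_length=600_000,
        inversion=(100_000, 500_000),
        mu=1.2e-6,
        r=2.5e-7,
        c=0.0,
        generations=250,
        n_init_fixed_diffs=500,
        seed=seed,
    )


def sweep_scenario(seed: int) -> SimConfig:
    """Recent strong sweep on the rearranged arrangement.

    The sweep site sits 50 kb inside the rearrangement boundary: with
    partial heterokaryotype recombination (``c=0.5``) arrangement-
    restricted selection only completes near the boundary, because
    recombination farther away constantly exchanges the selected allele
    between arrangement backgrounds.
    """
    return SimConfig(
        n_individuals=200,
        contig_length=1_550_000,
        inversion=(150_000, 1_550_000),
        mu=5e-7,
        r=2.5e-6,
        c=0.5,
        generations=80,
        n_init_fixed_diffs=0,
        init_theta_scale=4.0,
        seed=seed,
        sweep=SweepSpec(
            position=SWEEP_POSITION,
            arrangement="ZAL2m",
            s=1.0,
            start_gen=55,
            n_init_copies=16,
        ),
    )


def nfds_scenario(seed: int) -> SimConfig:
    """Balanced two-backbone region inside the rearrangement.

    A 50 kb region carries two divergent rearranged-haplotype backbones
    held near frequency 0.5 by negative frequency dependence, against a
    background of 5000 fixed differences across a 1 Mb rearrangement.
    """
    return SimConfig(
        n_individuals=200,
        contig_length=1_400_000,
        inversion=(200_000, 1_200_000),
        mu=6e-7,
        r=2.5e-7,
        c=0.0,
        generations=250,
        n_init_fixed_diffs=5000,
        init_theta_scale=4.0,
        seed=seed,
        balanced=BalancedSpec(
            region=NFDS_REGION, s_b=1.0, n_backbone=250, split=0.4
        ),
    )
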