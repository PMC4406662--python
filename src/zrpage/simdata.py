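"""Synthetic four-group expression experiments with known ground truth.

The generator emulates a two-strain x two-treatment microarray design
(default groups R1AL, P8AL, R1CR, P8CR: senescence-resistant vs
senescence-prone astrocytes under ad-libitum vs caloric-restriction
conditions, n = 3 replicate arrays per group) at chip scale (24 613
transcripts by default, matching a MouseRef-8 class array).

Signal model, on the log10-intensity scale per gene g and group:

    log10 x = baseline_g + strain + treatment + interaction
              + coherent-set shift + N(0, sigma_g)

and intensities are emitted as 10**signal, so the normalization stage's
log transform is exercised. The four groups are treated positionally as
the 2x2 crossing (control/control, strain/control, control/treatment,
strain/treatment): groups[1] and groups[3] carry the strain effect,
groups[2] and groups[3] the treatment effect, groups[3] alone the
interaction. Interaction effects are how discordant responses of the two
strains to treatment ("opposite direction" pathways) arise. Coherent
gene-set shifts act through the strain factor, so a coherent set is
detectable in the strain comparisons.

Per-gene noise scales sigma_g are drawn from a log-normal centred on
``noise_sd`` (mean-preserving), with ``noise_sd_spread = 0`` giving a
constant sigma; this produces a realistic mean-variance spread without
modeling any specific chip chemistry.

Randomness uses a single root seed split into four independent streams in
a fixed order (gene baselines -> factorial effects -> set membership ->
replicate noise), so e.g. changing the gene-set configuration never
perturbs the expression noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .normalize import SampleDesign
from .page import GeneSet, GeneSetCollection

DEFAULT_GROUPS = ("R1AL", "P8AL", "R1CR", "P8CR")
#: Comparisons for which truth records an expected direction: strain at
#: baseline, treatment within each strain, strain after treatment.
DEFAULT_COMPARISONS = ("P8AL-R1AL", "R1CR-R1AL", "P8CR-P8AL", "P8CR-R1CR")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Effects are log10-intensity offsets; a fraction of genes receives each
    factorial effect with a magnitude drawn from ``effect_sizes`` and a
    random sign. All fractions must lie in [0, 1].
    """

    n_genes: int = 24613
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates: int = 3
    baseline_mean: float = 2.5
    baseline_sd: float = 0.5
    noise_sd: float = 0.2
    noise_sd_spread: float = 0.25
    frac_strain_de: float = 0.05
    frac_treatment_de: float = 0.05
    frac_interaction_de: float = 0.02
    effect_sizes: tuple[float, ...] = (0.15, 0.3)
    n_sets: int = 1688
    set_size_range: tuple[int, int] = (10, 100)
    frac_coherent_sets: float = 0.1
    coherent_shift: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError(f"n_genes must be >= 2, got {self.n_genes}")
        if len(self.groups) != 4 or len(set(self.groups)) != 4:
            raise ValidationError(f"groups must be 4 distinct labels, got {self.groups}")
        if self.n_replicates < 2:
            raise ValidationError(f"n_replicates must be >= 2, got {self.n_replicates}")
        for name in ("frac_strain_de", "frac_treatment_de", "frac_interaction_de",
                     "frac_coherent_sets"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not self.effect_sizes or not all(
            np.isfinite(e) and e > 0 for e in self.effect_sizes
        ):
            raise ValidationError(f"effect_sizes must be finite and > 0, got {self.effect_sizes}")
        if self.baseline_sd <= 0 or self.noise_sd <= 0 or self.noise_sd_spread < 0:
            raise ValidationError("baseline_sd and noise_sd must be > 0, noise_sd_spread >= 0")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"set_size_range must satisfy 1 <= min <= max, got {self.set_size_range}")
        if self.n_sets < 0:
            raise ValidationError(f"n_sets must be >= 0, got {self.n_sets}")
        if not np.isfinite(self.coherent_shift):
            raise ValidationError(f"coherent_shift must be finite, got {self.coherent_shift}")

    # factor membership by position in the 2x2 crossing
    def strain_groups(self) -> tuple[str, str]:
        return (self.groups[1], self.groups[3])

    def treatment_groups(self) -> tuple[str, str]:
        return (self.groups[2], self.groups[3])

    def interaction_group(self) -> str:
        return self.groups[3]


@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    ``gene_effects`` holds signed log10 offsets per gene (columns strain,
    treatment, interaction, coherent); ``group_offsets`` the resulting
    noiseless offset of each group; ``expected_direction`` the implied
    up/down/null label per comparison; ``coherent_sets`` maps coherent set
    names to their shift sign.
    """

    gene_effects: pd.DataFrame
    group_offsets: pd.DataFrame
    expected_direction: pd.DataFrame
    coherent_sets: dict[str, int] = field(default_factory=dict)

    @property
    def n_affected_genes(self) -> int:
        return int((self.gene_effects.to_numpy() != 0).any(axis=1).sum())

    @property
    def is_null(self) -> bool:
        return self.n_affected_genes == 0 and not self.coherent_sets


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("genes", "effects", "sets", "noise")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _gene_ids(config: SimConfig) -> pd.Index:
    width = len(str(config.n_genes))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)],
                    name="gene_id")


def _draw_effect(rng: np.random.Generator, n: int, frac: float,
                 sizes: tuple[float, ...]) -> np.ndarray:
    """Signed per-gene effect vector; zero for unaffected genes."""
    mask = rng.random(n) < frac
    magnitude = np.asarray(sizes, dtype=float)[rng.integers(0, len(sizes), n)]
    sign = rng.choice([-1.0, 1.0], n)
    return np.where(mask, magnitude * sign, 0.0)


def make_design(config: SimConfig) -> SampleDesign:
    """Sample design with replicate ids ``<group>_<r>`` in group order."""
    assignments = {
        f"{g}_{r}": g
        for g in config.groups
        for r in range(1, config.n_replicates + 1)
    }
    return SampleDesign(assignments=assignments, groups=config.groups)


def generate_gene_sets(
    config: SimConfig, gene_ids
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Draw random gene sets and mark a fraction of them coherent.

    Returns the collection and a map ``set name -> shift sign`` for the
    coherent sets. Membership is drawn from the dedicated ``sets`` RNG
    stream of the root seed, so results match the combined entry point.
    """
    gene_ids = pd.Index(gene_ids)
    if gene_ids.empty:
        raise ValidationError("gene_ids must be nonempty")
    lo, hi = config.set_size_range
    if hi > len(gene_ids):
        raise ValidationError(
            f"set_size_range max {hi} exceeds number of genes {len(gene_ids)}"
        )
    rng = _streams(config)["sets"]
    width = len(str(max(config.n_sets, 1)))
    sets = []
    for i in range(1, config.n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(gene_ids.to_numpy(), size=size, replace=False))
        sets.append(GeneSet(name=f"SET{i:0{width}d}", description="synthetic",
                            members=members))
    n_coherent = int(round(config.frac_coherent_sets * config.n_sets))
    coherent: dict[str, int] = {}
    if n_coherent:
        chosen = rng.choice(config.n_sets, size=n_coherent, replace=False)
        signs = rng.choice([-1, 1], size=n_coherent)
        for idx, sign in zip(sorted(chosen), signs):
            coherent[sets[int(idx)].name] = int(sign)
    return GeneSetCollection(sets), coherent


def _coherent_gene_offsets(
    config: SimConfig, gene_ids: pd.Index,
    sets: GeneSetCollection, coherent: dict[str, int],
) -> pd.Series:
    """Per-gene coherent shift (log10), summed over coherent sets."""
    offsets = pd.Series(0.0, index=gene_ids)
    for name, sign in coherent.items():
        members = [g for g in sets[name].members if g in offsets.index]
        offsets.loc[members] += sign * config.coherent_shift
    return offsets


def generate_expression(
    config: SimConfig,
    coherent_offsets: pd.Series | None = None,
) -> tuple[pd.DataFrame, SampleDesign, SimTruth]:
    """Generate the raw intensity matrix, design and ground truth.

    ``coherent_offsets`` (per-gene log10 shifts applied through the strain
    factor) is supplied by :func:`simulate_experiment`; standalone calls
    generate expression without gene-set structure.
    """
    rngs = _streams(config)
    gene_ids = _gene_ids(config)
    design = make_design(config)

    baselines = rngs["genes"].normal(config.baseline_mean, config.baseline_sd,
                                     config.n_genes)
    if config.noise_sd_spread > 0:
        # mean-preserving log-normal: E[sigma_g] = noise_sd
        s = config.noise_sd_spread
        sigma = config.noise_sd * np.exp(
            rngs["genes"].normal(-0.5 * s * s, s, config.n_genes)
        )
    else:
        sigma = np.full(config.n_genes, config.noise_sd)

    eff = rngs["effects"]
    strain = _draw_effect(eff, config.n_genes, config.frac_strain_de, config.effect_sizes)
    treatment = _draw_effect(eff, config.n_genes, config.frac_treatment_de, config.effect_sizes)
    interaction = _draw_effect(eff, config.n_genes, config.frac_interaction_de, config.effect_sizes)
    coherent = (
        coherent_offsets.reindex(gene_ids).fillna(0.0).to_numpy()
        if coherent_offsets is not None
        else np.zeros(config.n_genes)
    )

    strain_total = strain + coherent
    in_strain = np.array([g in config.strain_groups() for g in config.groups])
    in_trt = np.array([g in config.treatment_groups() for g in config.groups])
    in_inter = np.array([g == config.interaction_group() for g in config.groups])
    group_offsets = (
        strain_total[:, None] * in_strain
        + treatment[:, None] * in_trt
        + interaction[:, None] * in_inter
    )

    noise = rngs["noise"].normal(
        0.0, 1.0, (config.n_genes, len(config.groups) * config.n_replicates)
    ) * sigma[:, None]
    per_sample_offset = np.repeat(group_offsets, config.n_replicates, axis=1)
    log10_signal = baselines[:, None] + per_sample_offset + noise
    raw = pd.DataFrame(
        np.power(10.0, log10_signal), index=gene_ids,
        columns=pd.Index(design.sample_ids, name="sample_id"),
    )

    offsets_df = pd.DataFrame(group_offsets, index=gene_ids,
                              columns=list(config.groups))
    truth = SimTruth(
        gene_effects=pd.DataFrame(
            {"strain": strain, "treatment": treatment,
             "interaction": interaction, "coherent": coherent},
            index=gene_ids,
        ),
        group_offsets=offsets_df,
        expected_direction=_expected_directions(offsets_df, config),
        coherent_sets={},
    )
    return raw, design, truth


def _expected_directions(group_offsets: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    from .diffexpr import ComparisonSpec  # local import to avoid cycle at import time

    out = {}
    for name in DEFAULT_COMPARISONS if config.groups == DEFAULT_GROUPS else _positional_comparisons(config):
        cmp = ComparisonSpec.parse(name)
        diff = group_offsets[cmp.experimental] - group_offsets[cmp.control]
        out[name] = np.where(diff > 0, "up", np.where(diff < 0, "down", "null"))
    return pd.DataFrame(out, index=group_offsets.index)


def _positional_comparisons(config: SimConfig) -> tuple[str, ...]:
    g = config.groups
    return (f"{g[1]}-{g[0]}", f"{g[2]}-{g[0]}", f"{g[3]}-{g[1]}", f"{g[3]}-{g[2]}")


@dataclass
class SimResult:
    """Bundle returned by the combined generator entry point."""

    raw: pd.DataFrame
    design: SampleDesign
    sets: GeneSetCollection
    truth: SimTruth


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate gene sets and expression together.

    Coherent-set shifts are folded into the expression signal (through the
    strain factor) and recorded in the truth, making coherent sets
    detectable by a mean-based enrichment statistic in the strain
    comparisons.
    """
    gene_ids = _gene_ids(config)
    sets, coherent = generate_gene_sets(config, gene_ids)
    offsets = _coherent_gene_offsets(config, gene_ids, sets, coherent)
    raw, design, truth = generate_expression(config, coherent_offsets=offsets)
    truth.coherent_sets = coherent
    return SimResult(raw=raw, design=design, sets=sets, truth=truth)
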