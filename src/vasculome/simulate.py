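"""Synthetic translatome / whole-tissue / single-cell data with known ground truth.

The generator emulates a cell-type-enriched bulk RNA-seq study across three
organs (brain, lung, heart), two compartments (endothelial-enriched "EC" and
whole tissue), an inflammatory time course, sequencing batches, and matching
droplet-style single-cell counts.  Every gene carries exactly one planted role:

``pan_endothelial``
    expressed well above whole-tissue level in the EC compartment of every
    organ, each gene with one *preferred* organ in which it is further
    elevated (as classical endothelial markers differ in level across beds);
``tissue_signature`` / ``surface_marker``
    elevated in the EC compartment of exactly one organ (surface markers are
    signature genes additionally listed in the surface-protein catalogue);
``parenchymal`` / ``adaptation``
    abundant in one organ's whole tissue; parenchymal genes are absent from
    the pure EC profile, while the adaptation subset is genuinely expressed
    in that organ's endothelium at a level drawn *independently* of its
    whole-tissue abundance (rank-decorrelated), so the endothelial rank of
    these genes differs from the parenchymal rank;
``housekeeping``
    identical expected abundance in every condition, with reduced biological
    dispersion;
``inflammatory``
    responds to the systemic challenge in one organ's endothelium following a
    planted kinetic pattern (transient or sustained, up or down);
``background``
    everything else, with EC and whole-tissue levels drawn independently.

Whole-tissue contamination of EC samples is a linear-scale mixture
``(1 - f) * EC_profile + f * whole_profile`` with a tunable fraction ``f`` —
the quantity the rank-correlation purity statistic is designed to detect.
Expected profiles are normalised to counts-per-million with the housekeeping
mass held fixed, so housekeeping genes have exactly constant expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ConfigurationError, DomainError

__all__ = [
    "TruthConfig",
    "SyntheticTruth",
    "build_truth",
    "simulate_bulk",
    "simulate_single_cell",
    "kinetic_multiplier",
    "KINETIC_PATTERNS",
]

CPM_TOTAL = 1e6

# log2-scale response shapes, anchored at 0 h and normalised to unit amplitude.
# Transient responses peak at 6 h and have fully recovered by 168 h; sustained
# responses reach their plateau at 24 h and hold it through 168 h.
_SHAPE_ANCHORS = {
    "transient_up": ((0.0, 6.0, 24.0, 48.0, 72.0, 168.0), (0.0, 1.0, 0.6, 0.35, 0.15, 0.0)),
    "sustained_up": ((0.0, 6.0, 24.0, 48.0, 72.0, 168.0), (0.0, 0.6, 1.0, 1.0, 1.0, 1.0)),
}

KINETIC_PATTERNS = ("stable", "transient_up", "transient_down", "sustained_up", "sustained_down")


def kinetic_multiplier(pattern: str, timepoint_h: float, amplitude_log2: float) -> float:
    """Linear-scale expression multiplier of one kinetic pattern at one timepoint.

    ``stable`` is identically 1; the other patterns scale a unit-amplitude
    log2 shape by ``amplitude_log2`` (e.g. ``transient_up`` at 6 h with
    amplitude 2 gives ``2**2 = 4``).
    """
    if pattern == "stable":
        return 1.0
    sign = 1.0
    base = pattern
    if pattern.endswith("_down"):
        sign = -1.0
        base = pattern.replace("_down", "_up")
    if base not in _SHAPE_ANCHORS:
        raise DomainError(f"unknown kinetic pattern {pattern!r}; expected one of {KINETIC_PATTERNS}")
    t_anchor, s_anchor = _SHAPE_ANCHORS[base]
    shape = float(np.interp(timepoint_h, t_anchor, s_anchor))
    return float(2.0 ** (sign * amplitude_log2 * shape))


@dataclass(frozen=True)
class TruthConfig:
    """Study-design and effect-size parameters of the synthetic experiment.

    Effect sizes are in log2 units; ``dispersion`` is the negative-binomial
    dispersion (variance = m + dispersion * m^2).  Housekeeping genes use
    ``dispersion * housekeeping_dispersion_factor`` — a stably expressed gene
    must be plantable as genuinely invariable for the housekeeping-selection
    rule to have a recoverable optimum.
    """

    n_genes: int = 2000
    tissues: tuple[str, ...] = ("brain", "lung", "heart")
    n_signature_per_tissue: int = 100
    n_parenchymal_per_tissue: int = 150
    adaptation_fraction: float = 0.2
    contamination_fraction_f: float = 0.05
    signature_effect_log2: float = 2.0
    dispersion: float = 0.02
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 24.0, 48.0, 72.0, 168.0)
    n_reps: int = 3
    n_batches: int = 3
    batch_shift_log2: float = 1.0
    library_size: int = 1_000_000
    seed: int = 0
    # additional planted-role budgets and effect sizes
    n_pan_endothelial: int = 152
    n_housekeeping: int = 20
    n_surface_per_tissue: int = 20
    n_inflammatory_per_tissue: int = 20
    pan_effect_log2: float = 3.0
    pan_tissue_effect_log2: float = 1.5
    parenchymal_effect_log2: float = 3.0
    kinetic_amplitude_log2: float = 2.0
    base_mean_log2: float = 5.0
    base_sd_log2: float = 1.5
    housekeeping_level_log2: float = 9.0
    housekeeping_dispersion_factor: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction_f <= 1.0:
            raise DomainError("contamination_fraction_f must lie in [0, 1]")
        if not 0.0 <= self.adaptation_fraction <= 1.0:
            raise DomainError("adaptation_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise DomainError("dispersion must be positive")
        if self.signature_effect_log2 <= 0:
            raise DomainError("signature_effect_log2 must be positive")
        if self.library_size <= 0:
            raise DomainError("library_size must be positive")
        if 0.0 not in self.timepoints_h:
            raise ConfigurationError("timepoints_h must include the 0 h baseline")
        n_t = len(self.tissues)
        used = (
            self.n_pan_endothelial
            + self.n_housekeeping
            + n_t * (self.n_signature_per_tissue + self.n_parenchymal_per_tissue
                     + self.n_surface_per_tissue + self.n_inflammatory_per_tissue)
        )
        if used > self.n_genes:
            raise ConfigurationError(
                f"role budgets need {used} genes but n_genes={self.n_genes}; reduce "
                "per-tissue signature/parenchymal/surface/inflammatory counts"
            )

    def n_adaptation_per_tissue(self) -> int:
        return int(round(self.adaptation_fraction * self.n_parenchymal_per_tissue))


@dataclass
class SyntheticTruth:
    """Ground truth: gene roles, expected profiles, contamination, kinetics.

    ``roles`` assigns every gene exactly one of the role labels; tissue-bound
    roles carry their tissue in ``role_tissue``.  ``ec_level_log2`` /
    ``whole_level_log2`` hold the *unnormalised* expected log2 abundance per
    gene per tissue (``-inf`` encodes absence); :meth:`expected_cpm` converts
    them to housekeeping-preserving CPM profiles, applies kinetic multipliers
    and the EC contamination mixture.
    """

    config: TruthConfig
    gene_ids: pd.Index
    roles: pd.Series                      # gene -> role label
    role_tissue: pd.Series                # gene -> tissue or ""
    ec_level_log2: pd.DataFrame           # gene x tissue (pure EC, baseline)
    whole_level_log2: pd.DataFrame        # gene x tissue
    housekeeping_cpm: pd.Series           # fixed CPM of housekeeping genes
    kinetic_patterns: dict = field(default_factory=dict)  # (gene, tissue) -> pattern
    pan_preferred_tissue: pd.Series = None  # pan-EC gene -> preferred tissue
    batch_shifts_log2: pd.DataFrame = None  # gene x batch log2 shifts
    contamination_fraction_f: float = 0.0
    kinetic_amplitude_log2: float = 2.0

    # -- role accessors --------------------------------------------------------

    def genes_with_role(self, role: str, tissue: str | None = None) -> list[str]:
        mask = self.roles == role
        if tissue is not None:
            mask &= self.role_tissue == tissue
        return list(self.gene_ids[mask])

    @property
    def housekeeping_genes(self) -> list[str]:
        return self.genes_with_role("housekeeping")

    @property
    def pan_endothelial_genes(self) -> list[str]:
        return self.genes_with_role("pan_endothelial")

    def signature_genes(self, tissue: str) -> list[str]:
        return self.genes_with_role("tissue_signature", tissue)

    def surface_genes(self, tissue: str) -> list[str]:
        return self.genes_with_role("surface_marker", tissue)

    def parenchymal_genes(self, tissue: str) -> list[str]:
        """Parenchymal genes of a tissue, including the adaptation subset."""
        return self.genes_with_role("parenchymal", tissue) + self.adaptation_genes(tissue)

    def adaptation_genes(self, tissue: str) -> list[str]:
        return self.genes_with_role("adaptation", tissue)

    def inflammatory_genes(self, tissue: str | None = None) -> list[str]:
        return self.genes_with_role("inflammatory", tissue)

    @property
    def surface_catalog(self) -> list[str]:
        return list(self.gene_ids[self.roles == "surface_marker"])

    @property
    def ec_marker_genes(self) -> list[str]:
        """Two highly expressed pan-endothelial genes used for cell selection."""
        pan = self.pan_endothelial_genes
        levels = self.ec_level_log2.loc[pan].min(axis=1)
        return list(levels.sort_values(ascending=False).index[:2])

    def ec_de_genes(self, tissue: str) -> set[str]:
        """All genes planted to be upregulated in one tissue's EC compartment
        relative to the other tissues' EC compartments (signature, surface,
        adaptation, and pan-endothelial genes preferring that tissue)."""
        out = set(self.signature_genes(tissue)) | set(self.surface_genes(tissue))
        out |= set(self.adaptation_genes(tissue))
        out |= set(self.pan_preferred_tissue.index[self.pan_preferred_tissue == tissue])
        return out

    def kinetic_pattern(self, gene: str, tissue: str) -> str:
        return self.kinetic_patterns.get((gene, tissue), "stable")

    # -- expected profiles -----------------------------------------------------

    def _normalize(self, linear: np.ndarray) -> np.ndarray:
        """Scale non-housekeeping mass so the profile sums to 1e6 CPM while
        housekeeping genes keep their fixed expected CPM."""
        cpm = np.zeros_like(linear)
        hk_mask = (self.roles == "housekeeping").to_numpy()
        hk_total = float(self.housekeeping_cpm.sum())
        other_total = linear[~hk_mask].sum()
        cpm[~hk_mask] = linear[~hk_mask] * (CPM_TOTAL - hk_total) / other_total
        cpm[hk_mask] = self.housekeeping_cpm.reindex(self.gene_ids[hk_mask]).to_numpy()
        return cpm

    def _pure_cpm(self, tissue: str, compartment: str, timepoint_h: float) -> np.ndarray:
        levels = (self.ec_level_log2 if compartment == "EC" else self.whole_level_log2)[tissue]
        with np.errstate(over="ignore"):
            linear = np.where(np.isneginf(levels.to_numpy()), 0.0, 2.0 ** levels.to_numpy())
        if compartment == "EC" and timepoint_h != 0.0:
            for (gene, t), pattern in self.kinetic_patterns.items():
                if t == tissue:
                    idx = self.gene_ids.get_loc(gene)
                    linear[idx] *= kinetic_multiplier(pattern, timepoint_h, self.kinetic_amplitude_log2)
        return self._normalize(linear)

    def expected_cpm(
        self,
        tissue: str,
        compartment: str,
        timepoint_h: float = 0.0,
        contamination: float | None = None,
    ) -> pd.Series:
        """Expected CPM profile of one condition (sums to 1e6).

        EC profiles are the contamination mixture
        ``(1 - f) * pure_EC + f * whole_tissue`` on the linear scale.
        """
        if compartment not in ("EC", "whole"):
            raise DomainError(f"unknown compartment {compartment!r}")
        f = self.contamination_fraction_f if contamination is None else contamination
        if not 0.0 <= f <= 1.0:
            raise DomainError("contamination fraction must lie in [0, 1]")
        whole = self._pure_cpm(tissue, "whole", timepoint_h)
        if compartment == "whole":
            return pd.Series(whole, index=self.gene_ids)
        ec = self._pure_cpm(tissue, "EC", timepoint_h)
        mixed = (1.0 - f) * ec + f * whole
        # the mixture is exact for housekeeping genes; avoid float drift
        hk_mask = (self.roles == "housekeeping").to_numpy()
        mixed[hk_mask] = self.housekeeping_cpm.reindex(self.gene_ids[hk_mask]).to_numpy()
        return pd.Series(mixed, index=self.gene_ids)

    def gene_dispersions(self) -> pd.Series:
        disp = pd.Series(self.config.dispersion, index=self.gene_ids)
        disp[self.roles == "housekeeping"] *= self.config.housekeeping_dispersion_factor
        return disp


def build_truth(config: TruthConfig) -> SyntheticTruth:
    """Assign gene roles and draw expected expression levels (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    tissues = list(config.tissues)
    gene_ids = pd.Index([f"g{i:04d}" for i in range(n)], name="gene")

    order = rng.permutation(n)
    roles = pd.Series("background", index=gene_ids)
    role_tissue = pd.Series("", index=gene_ids)
    cursor = 0

    def take(count: int) -> pd.Index:
        nonlocal cursor
        sel = gene_ids[order[cursor : cursor + count]]
        cursor += count
        return sel

    pan = take(config.n_pan_endothelial)
    hk = take(config.n_housekeeping)
    roles[pan] = "pan_endothelial"
    roles[hk] = "housekeeping"
    per_tissue: dict[str, dict[str, pd.Index]] = {}
    n_adapt = config.n_adaptation_per_tissue()
    for t in tissues:
        sig = take(config.n_signature_per_tissue)
        surf = take(config.n_surface_per_tissue)
        parench = take(config.n_parenchymal_per_tissue - n_adapt)
        adapt = take(n_adapt)
        infl = take(config.n_inflammatory_per_tissue)
        for idx, label in ((sig, "tissue_signature"), (surf, "surface_marker"),
                           (parench, "parenchymal"), (adapt, "adaptation"),
                           (infl, "inflammatory")):
            roles[idx] = label
            role_tissue[idx] = t
        per_tissue[t] = {"sig": sig, "surf": surf, "parench": parench, "adapt": adapt, "infl": infl}

    # base abundances: EC and whole-tissue levels drawn independently — the
    # endothelial abundance rank of a generic gene is unrelated to its
    # whole-tissue rank, which is what a pure cell-type-enriched profile
    # looks like next to whole tissue
    base_ec = rng.normal(config.base_mean_log2, config.base_sd_log2, n)
    base_whole = rng.normal(config.base_mean_log2, config.base_sd_log2, n)
    ec_levels = pd.DataFrame({t: base_ec.copy() for t in tissues}, index=gene_ids)
    whole_levels = pd.DataFrame({t: base_whole.copy() for t in tissues}, index=gene_ids)

    hk_level = rng.normal(config.housekeeping_level_log2, 0.5, config.n_housekeeping)
    ec_levels.loc[hk] = np.repeat(hk_level[:, None], len(tissues), axis=1)
    whole_levels.loc[hk] = np.repeat(hk_level[:, None], len(tissues), axis=1)
    housekeeping_cpm = pd.Series(2.0 ** hk_level, index=hk)

    # pan-endothelial: elevated in EC everywhere, further elevated in one
    # preferred organ (classical markers differ in level across beds)
    ec_levels.loc[pan] += config.pan_effect_log2
    preferred = pd.Series(
        [tissues[i % len(tissues)] for i in range(len(pan))], index=pan
    ).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    preferred = pd.Series(preferred.to_numpy(), index=pan)
    for t in tissues:
        ec_levels.loc[preferred.index[preferred == t], t] += config.pan_tissue_effect_log2

    for t in tissues:
        info = per_tissue[t]
        ec_levels.loc[info["sig"], t] += config.signature_effect_log2
        ec_levels.loc[info["surf"], t] += config.signature_effect_log2
        # parenchymal: abundant in this organ's whole tissue, absent from the
        # pure endothelial profile everywhere
        whole_levels.loc[info["parench"], t] += config.parenchymal_effect_log2
        whole_levels.loc[info["adapt"], t] += config.parenchymal_effect_log2
        for tt in tissues:
            ec_levels.loc[info["parench"], tt] = -np.inf
            ec_levels.loc[info["adapt"], tt] = -np.inf
        # adaptation: genuinely expressed in this organ's EC at a level drawn
        # independently of the whole-tissue abundance (rank-decorrelated)
        if len(info["adapt"]):
            ec_levels.loc[info["adapt"], t] = rng.normal(
                config.base_mean_log2, config.base_sd_log2, len(info["adapt"])
            )
        # inflammatory responders: well expressed so their kinetics are measurable
        ec_levels.loc[info["infl"]] = rng.normal(7.0, 1.0, len(info["infl"]))[:, None]

    kinetic_patterns: dict[tuple[str, str], str] = {}
    nonstable = [p for p in KINETIC_PATTERNS if p != "stable"]
    for t in tissues:
        for j, gene in enumerate(per_tissue[t]["infl"]):
            kinetic_patterns[(gene, t)] = nonstable[j % len(nonstable)]

    # gene-wise batch effects (log2): a shift common to all genes would be
    # absorbed by depth normalisation, so real batch structure is per gene
    shifts = np.zeros((n, config.n_batches))
    if config.n_batches > 1 and config.batch_shift_log2 != 0.0:
        shifts[:, 1:] = rng.normal(0.0, abs(config.batch_shift_log2), (n, config.n_batches - 1))
    batch_shifts = pd.DataFrame(
        shifts, index=gene_ids, columns=[f"b{i}" for i in range(config.n_batches)]
    )

    return SyntheticTruth(
        config=config,
        gene_ids=gene_ids,
        roles=roles,
        role_tissue=role_tissue,
        ec_level_log2=ec_levels,
        whole_level_log2=whole_levels,
        housekeeping_cpm=housekeeping_cpm,
        kinetic_patterns=kinetic_patterns,
        pan_preferred_tissue=preferred,
        batch_shifts_log2=batch_shifts,
        contamination_fraction_f=config.contamination_fraction_f,
        kinetic_amplitude_log2=config.kinetic_amplitude_log2,
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative-binomial draw with mean m and variance m + dispersion * m^2
    via the gamma-Poisson mixture (per-gene dispersions supported)."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    lam = np.where(
        disp > 0,
        rng.gamma(np.maximum(1.0 / np.maximum(disp, 1e-300), 1e-12), disp * mean + 1e-300),
        mean,
    )
    return rng.poisson(np.where(mean > 0, lam, 0.0))


def simulate_bulk(
    truth: SyntheticTruth, config: TruthConfig | None = None, seed: int | None = None
) -> ExpressionMatrix:
    """Simulate the bulk study: counts for every tissue x compartment x
    timepoint x replicate, with batch effects applied as log2 shifts.

    EC sample expectations are the contamination mixture
    ``(1 - f) * EC + f * whole`` on the linear CPM scale; counts are
    negative-binomial around expected CPM x library_size / 1e6.
    """
    config = config or truth.config
    if not 0.0 <= config.contamination_fraction_f <= 1.0:
        raise DomainError("contamination_fraction_f must lie in [0, 1]")
    rng = np.random.default_rng([config.seed if seed is None else seed, 1])
    dispersions = truth.gene_dispersions().to_numpy()
    batch_mult = 2.0 ** truth.batch_shifts_log2.to_numpy()       # genes x batches
    rows = []
    sample_ids = []
    meta = []
    sample_idx = 0
    for tissue in config.tissues:
        for compartment in ("EC", "whole"):
            for tp in config.timepoints_h:
                cpm = truth.expected_cpm(
                    tissue, compartment, tp, contamination=config.contamination_fraction_f
                ).to_numpy()
                for rep in range(1, config.n_reps + 1):
                    batch = sample_idx % config.n_batches
                    mean = cpm * config.library_size / CPM_TOTAL * batch_mult[:, batch]
                    rows.append(_nb_counts(rng, mean, dispersions))
                    sid = f"{tissue}_{compartment}_t{int(tp):03d}_r{rep}"
                    sample_ids.append(sid)
                    meta.append(
                        {
                            "tissue": tissue,
                            "compartment": compartment,
                            "timepoint_h": float(tp),
                            "batch": f"b{batch}",
                            "platform": "bulk",
                            "replicate": rep,
                        }
                    )
                    sample_idx += 1
    values = pd.DataFrame(
        np.column_stack(rows), index=truth.gene_ids, columns=pd.Index(sample_ids, name="sample_id")
    )
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values=values, samples=samples, scale="counts")


def simulate_single_cell(
    truth: SyntheticTruth,
    n_cells_per_tissue: int = 300,
    capture_rate: float = 0.3,
    seed: int = 0,
    ec_fraction: float = 0.8,
    mean_library: float = 5000.0,
    library_sigma_log: float = 0.3,
) -> ExpressionMatrix:
    """Simulate droplet-style sparse single-cell counts per tissue.

    A fraction ``ec_fraction`` of cells are endothelial (pure EC expected
    profile, no whole-tissue contamination); the rest are parenchymal cells
    carrying the whole-tissue profile with all pan-endothelial genes zeroed,
    so marker-based double-positive selection is exercised.  Counts are
    Poisson draws around per-cell rates thinned by ``capture_rate``; per-cell
    library sizes are log-normal.
    """
    if not 0.0 < capture_rate <= 1.0:
        raise DomainError("capture_rate must lie in (0, 1]")
    if n_cells_per_tissue < 1:
        raise DomainError("n_cells_per_tissue must be >= 1")
    rng = np.random.default_rng([seed, 2])
    pan_mask = (truth.roles == "pan_endothelial").to_numpy()
    sig_mask = (truth.roles.isin(["tissue_signature", "surface_marker"])).to_numpy()
    cols = []
    ids = []
    meta = []
    for tissue in truth.config.tissues:
        ec_cpm = truth.expected_cpm(tissue, "EC", 0.0, contamination=0.0).to_numpy()
        whole = truth.expected_cpm(tissue, "whole", 0.0).to_numpy().copy()
        whole[pan_mask] = 0.0        # parenchymal cells carry no endothelial markers
        whole[sig_mask] = 0.0
        n_ec = int(round(ec_fraction * n_cells_per_tissue))
        libs = np.exp(rng.normal(np.log(mean_library), library_sigma_log, n_cells_per_tissue))
        for j in range(n_cells_per_tissue):
            is_ec = j < n_ec
            profile = ec_cpm if is_ec else whole
            rate = profile / CPM_TOTAL * libs[j] * capture_rate
            cols.append(rng.poisson(rate))
            ids.append(f"{tissue}_c{j:04d}")
            meta.append({"tissue": tissue, "cell_type": "EC" if is_ec else "parenchymal",
                         "platform": "droplet_sc"})
    values = pd.DataFrame(
        np.column_stack(cols), index=truth.gene_ids, columns=pd.Index(ids, name="cell_id")
    )
    samples = pd.DataFrame(meta, index=pd.Index(ids, name="cell_id"))
    return ExpressionMatrix(values=values, samples=samples, scale="counts")


def with_overrides(config: TruthConfig, **kwargs) -> TruthConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return dataclasses.replace(config, **kwargs)
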