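"""Synthetic expression and IHC data with planted, recoverable structure.

The generator emulates the study design the pipeline targets: two
surgical groups (sham-operated and immobilized), capsules harvested at
weeks 1, 2, 4, 8 and 16, four arrays per group per week, on a chip of
~31k probe sets summarized MAS5-style with Present/Marginal/Absent
calls and intensities scaled so the trimmed mean is 100.

Structure is planted in log2-ratio space: each probe belongs to a
trajectory cluster given by polynomial coefficients over standardized
time; intensities are log-normal around a per-probe baseline modulated
by the trajectory, with i.i.d. log2 replicate noise.  A configured
fraction of probes is called Absent on every array (they still carry
positive intensities: absence is a call, not a zero), and a configured
fraction of the remainder has every weekly median below the expression
floor — together these exercise the two filtering rules with exact,
known counts.  Absent and below-floor probes are drawn from the flattest
trajectories first: unexpressed probes are by nature not the
dynamically responding ones, and this keeps the planted dynamic clusters
intact for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .cluster import standardized_design
from .dataset import ExpressionDataset
from .errors import ConfigurationError


def coeffs_from_trajectory(values, weeks=(2, 4, 8, 16)) -> tuple:
    """Order-(T-1) polynomial coefficients hitting the given log2 ratios.

    With as many coefficients as post-baseline weeks the Vandermonde
    system is square, so any trajectory is representable exactly; this
    lets cluster specs be written as the intended center values.
    """
    X = standardized_design(weeks, order=len(weeks) - 1)
    return tuple(np.linalg.solve(X, np.asarray(values, dtype=float)))


@dataclass
class SimulationConfig:
    """Study-design and noise settings for the expression generator.

    ``cluster_spec`` is a list of ``(coefficients, member_count)`` pairs
    — polynomial coefficients in log2-ratio space over standardized time
    (see :func:`coeffs_from_trajectory`) — or a mapping group ->
    such a list when the two series should differ.  Member counts must
    sum to ``n_probes``.  Proportion defaults mirror the reference
    design: 5616/31099 all-absent, 8771/25483 of the survivors below the
    floor of 100.
    """

    n_probes: int = 31099
    n_replicates_per_cell: int = 4
    weeks: tuple = (1, 2, 4, 8, 16)
    cluster_spec: object = None
    groups: tuple = ("sham", "immobilized")
    baseline_log_intensity_mean: float = 8.0  # log2 scale
    baseline_log_intensity_sd: float = 1.0
    replicate_noise_sd: float = 0.1  # log2 scale
    absent_fraction: float = 5616 / 31099
    low_floor_fraction: float = 8771 / 25483
    marginal_call_rate: float = 0.02
    sporadic_absent_rate: float = 0.01
    target_intensity: float = 100.0
    expression_floor: float = 100.0
    protect_dynamic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_spec is None:
            flat = coeffs_from_trajectory(
                [0.0] * (len(self.weeks) - 1), self.weeks[1:]
            )
            self.cluster_spec = [(flat, self.n_probes)]
        self.validate()

    def spec_for(self, group: str) -> list:
        spec = self.cluster_spec
        if isinstance(spec, dict):
            if group not in spec:
                raise ConfigurationError(f"no cluster_spec for group {group!r}")
            return list(spec[group])
        return list(spec)

    def validate(self) -> None:
        if self.n_probes <= 0 or self.n_replicates_per_cell <= 0:
            raise ConfigurationError("n_probes and replicates must be positive")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ConfigurationError("weeks must be strictly increasing")
        for frac, name in (
            (self.absent_fraction, "absent_fraction"),
            (self.low_floor_fraction, "low_floor_fraction"),
            (self.marginal_call_rate, "marginal_call_rate"),
            (self.sporadic_absent_rate, "sporadic_absent_rate"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.replicate_noise_sd <= 0 or self.baseline_log_intensity_sd <= 0:
            raise ConfigurationError("noise standard deviations must be > 0")
        for group in self.groups:
            spec = self.spec_for(group)
            total = sum(count for _, count in spec)
            if total != self.n_probes:
                raise ConfigurationError(
                    f"cluster member counts for {group!r} sum to {total}, "
                    f"expected n_probes={self.n_probes}"
                )


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run.

    ``labels``: per group, a Series probe id -> planted label.  Dynamic
    trajectory clusters are labeled ``C1, C2, ...`` in spec order;
    probes overridden to all-absent or below-floor carry the labels
    ``__absent__`` / ``__low__``.  ``true_centers``: per group, a
    cluster x week DataFrame of planted log2-ratio trajectories.
    """

    labels: dict = dfield(default_factory=dict)
    true_centers: dict = dfield(default_factory=dict)
    absent_probes: set = dfield(default_factory=set)
    low_floor_probes: set = dfield(default_factory=set)

    def dynamic_labels(self, group: str, min_amplitude: float = 0.0) -> pd.Series:
        """Labels restricted to non-overridden probes in clusters whose
        planted amplitude exceeds ``min_amplitude``."""
        lab = self.labels[group]
        lab = lab[~lab.isin(["__absent__", "__low__"])]
        if min_amplitude > 0:
            centers = self.true_centers[group]
            keep = centers.abs().max(axis=1) > min_amplitude
            lab = lab[lab.isin(centers.index[keep])]
        return lab

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for group, lab in self.labels.items():
            frames.append(
                pd.DataFrame(
                    {"probe_id": lab.index, "group": group, "cluster_label": lab.values}
                )
            )
        return pd.concat(frames, ignore_index=True)


def _trimmed_mean(values: np.ndarray, trim: float = 0.02) -> float:
    v = np.sort(values.ravel())
    k = int(len(v) * trim)
    return float(v[k: len(v) - k].mean())


def generate_expression_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, PlantedTruth]:
    """Generate a two-group expression dataset with planted structure.

    Postconditions: intensities strictly positive; exactly
    ``round(absent_fraction * n_probes)`` probes are called "A" in every
    sample (of both groups); exactly ``round(low_floor_fraction *
    remaining)`` probes have every per-group weekly median below the
    floor; every other probe follows ``baseline * 2^(trajectory +
    noise)`` and is guaranteed at least one present call and one weekly
    median at or above the floor.  Identical config and seed yield
    byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    weeks = list(config.weeks)
    ratio_weeks = weeks[1:]
    digits = max(5, len(str(n)))
    probes = pd.Index(
        [f"P{i:0{digits}d}" for i in range(1, n + 1)], name="probe_id"
    )

    # -- planted labels per group ----------------------------------------
    truth = PlantedTruth()
    group_traj = {}
    for group in config.groups:
        spec = config.spec_for(group)
        labels = np.empty(n, dtype=object)
        traj = np.zeros((n, len(ratio_weeks)))
        centers = {}
        pos = 0
        for ci, (coeffs, count) in enumerate(spec, start=1):
            coeffs = np.asarray(coeffs, dtype=float)
            Xc = standardized_design(ratio_weeks, order=len(coeffs) - 1)
            center = Xc @ coeffs
            name = f"C{ci}"
            labels[pos: pos + count] = name
            traj[pos: pos + count] = center
            centers[name] = center
            pos += count
        truth.labels[group] = pd.Series(labels, index=probes)
        truth.true_centers[group] = pd.DataFrame(
            centers, index=ratio_weeks
        ).T
        group_traj[group] = traj

    # -- choose absent / below-floor probes (shared across groups) -------
    n_absent = round(config.absent_fraction * n)
    n_low = round(config.low_floor_fraction * (n - n_absent))
    if config.protect_dynamic:
        # flattest planted trajectories first, over both groups
        amp = np.max(
            [np.abs(group_traj[g]).max(axis=1) for g in config.groups], axis=0
        )
        order = np.lexsort((np.arange(n), amp))  # stable: amplitude, then index
    else:
        order = rng.permutation(n)
    absent_idx = np.sort(order[:n_absent])
    low_idx = np.sort(order[n_absent: n_absent + n_low])
    truth.absent_probes = set(probes[absent_idx])
    truth.low_floor_probes = set(probes[low_idx])
    for group in config.groups:
        truth.labels[group].iloc[absent_idx] = "__absent__"
        truth.labels[group].iloc[low_idx] = "__low__"

    # -- intensities and calls per group ---------------------------------
    nrep = config.n_replicates_per_cell
    floor = config.expression_floor
    sample_cols, meta_rows = [], []
    intens_blocks, call_blocks = [], []
    traj_mask = np.ones(n, dtype=bool)
    traj_mask[absent_idx] = False
    traj_mask[low_idx] = False
    for group in config.groups:
        baseline = rng.normal(
            config.baseline_log_intensity_mean,
            config.baseline_log_intensity_sd,
            size=n,
        )
        traj = group_traj[group]
        log2I = np.empty((n, len(weeks) * nrep))
        cols, metas = [], []
        for wi, week in enumerate(weeks):
            delta = np.zeros(n) if week == weeks[0] else traj[:, wi - 1]
            for rep in range(1, nrep + 1):
                noise = rng.normal(0.0, config.replicate_noise_sd, size=n)
                log2I[:, wi * nrep + rep - 1] = baseline + delta + noise
                sid = f"{group}_w{week}_r{rep}"
                cols.append(sid)
                metas.append({"sample_id": sid, "group": group,
                              "week": week, "replicate": rep})
        intens = np.exp2(log2I)
        # MAS5-style global scaling to the target trimmed mean
        intens *= config.target_intensity / _trimmed_mean(intens)
        # below-floor probes: every weekly median strictly below the floor
        if n_low:
            low_vals = rng.uniform(
                0.2 * floor, 0.95 * floor, size=(n_low, intens.shape[1])
            )
            intens[low_idx] = low_vals
        # guarantee trajectory probes are not all-below-floor
        med = np.stack(
            [
                np.median(intens[:, wi * nrep: (wi + 1) * nrep], axis=1)
                for wi in range(len(weeks))
            ],
            axis=1,
        )
        all_below = traj_mask & (med < floor).all(axis=1)
        if all_below.any():
            bump = (1.05 * floor) / med[all_below].max(axis=1)
            intens[all_below] *= bump[:, None]

        calls = np.full(intens.shape, "P", dtype=object)
        u = rng.random(intens.shape)
        calls[u < config.sporadic_absent_rate] = "A"
        calls[
            (u >= config.sporadic_absent_rate)
            & (u < config.sporadic_absent_rate + config.marginal_call_rate)
        ] = "M"
        calls[absent_idx, :] = "A"
        # guarantee non-absent probes keep >= 1 present call
        non_absent = np.ones(n, dtype=bool)
        non_absent[absent_idx] = False
        stuck = non_absent & (calls == "A").all(axis=1)
        calls[stuck, 0] = "P"

        sample_cols.extend(cols)
        meta_rows.extend(metas)
        intens_blocks.append(intens)
        call_blocks.append(calls)

    intensities = pd.DataFrame(
        np.hstack(intens_blocks), index=probes, columns=sample_cols
    )
    calls = pd.DataFrame(
        np.hstack(call_blocks), index=probes, columns=sample_cols
    )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    dataset = ExpressionDataset(intensities, calls, samples)
    return dataset, truth


def generate_probe_gene_map(
    probe_ids, probes_per_gene=None, seed: int = 0, prefix: str = "GENE"
) -> pd.DataFrame:
    """Assign gene symbols to probes, many-probes-to-one-gene.

    ``probes_per_gene`` is a sequence of group sizes consumed in order
    (cycled); by default ~30% of genes own two probes, the rest one,
    mimicking the redundancy of expression arrays.  Returns a two-column
    DataFrame (probe_id, gene_symbol).
    """
    rng = np.random.default_rng(seed)
    probe_ids = list(probe_ids)
    sizes = list(probes_per_gene) if probes_per_gene else None
    rows = []
    gi = 0
    i = 0
    while i < len(probe_ids):
        gi += 1
        if sizes:
            size = sizes[(gi - 1) % len(sizes)]
        else:
            size = 2 if rng.random() < 0.3 else 1
        size = min(size, len(probe_ids) - i)
        gene = f"{prefix}{gi:06d}"
        for p in probe_ids[i: i + size]:
            rows.append({"probe_id": p, "gene_symbol": gene})
        i += size
    return pd.DataFrame(rows)


def generate_gene_sets(
    genes,
    n_terms: int = 20,
    term_size: tuple = (10, 60),
    seed: int = 0,
    enriched: dict | None = None,
    source: str = "synthetic",
):
    """Random gene-set collection, optionally with planted enriched terms.

    ``enriched`` maps term name -> explicit gene list (e.g. drawn mostly
    from one planted cluster) added on top of ``n_terms`` random terms.
    Returns a :class:`~capsuledyn.enrichment.GeneSetCollection`.
    """
    from .enrichment import GeneSetCollection

    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets = {}
    for t in range(1, n_terms + 1):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        size = min(size, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"TERM{t:03d}"] = {genes[i] for i in members}
    for name, members in (enriched or {}).items():
        sets[name] = set(members)
    return GeneSetCollection(sets=sets, source=source)


def generate_ihc_dataset(
    n_rats_per_cell: int,
    group_effects: dict,
    examiner_sd: float,
    seed: int = 0,
    n_fields: int = 4,
    field_sd: float = 5.0,
) -> pd.DataFrame:
    """Two-examiner IHC percent-positive counts with known group means.

    ``group_effects`` maps ``(group, week)`` to the mean percent of
    DAB-positive cells for that cell of the design.  Each rat contributes
    ``n_fields`` fields; each field has a latent score (group mean plus
    Normal(0, field_sd) biological variation, clipped to [0, 100]) read
    by two examiners with independent Normal(0, examiner_sd) error,
    clipped to [0, 100].  With ``examiner_sd = 0`` the two examiners
    agree exactly.  Reproducible under the seed.
    """
    if examiner_sd < 0 or field_sd < 0:
        raise ConfigurationError("standard deviations must be >= 0")
    if n_rats_per_cell <= 0 or n_fields < 2:
        raise ConfigurationError("need >= 1 rat per cell and >= 2 fields")
    for (group, week), mean in group_effects.items():
        if not 0.0 <= mean <= 100.0:
            raise ConfigurationError(
                f"mean for ({group!r}, {week}) outside [0, 100]"
            )
    rng = np.random.default_rng(seed)
    rows = []
    rat_no = 0
    for (group, week), mean in group_effects.items():
        for _ in range(n_rats_per_cell):
            rat_no += 1
            rat = f"rat{rat_no:03d}"
            for fld in range(1, n_fields + 1):
                latent = float(
                    np.clip(mean + rng.normal(0.0, field_sd), 0.0, 100.0)
                ) if field_sd > 0 else float(mean)
                for examiner in (1, 2):
                    err = rng.normal(0.0, examiner_sd) if examiner_sd > 0 else 0.0
                    rows.append(
                        {
                            "rat": rat, "group": group, "week": week,
                            "field": fld, "examiner": examiner,
                            "percent": float(np.clip(latent + err, 0.0, 100.0)),
                        }
                    )
    return pd.DataFrame(rows)
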