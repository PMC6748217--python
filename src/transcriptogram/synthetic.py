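"""Synthetic data with planted ground truth for pipeline validation.

The generators emulate the statistical structure the pipeline assumes: a
PPI-like network with planted co-functional modules (a planted-partition
graph), case/control expression on the log-CPM scale with module-level mean
shifts and Gaussian noise, annotation terms aligned to the modules, and a
blocked time course for the sample-grouping stage.  Every generator is a pure
function of its parameters and seed.

The default "demo" scenario -- 6 modules x 50 genes, p_in = 0.25,
p_out = 0.01, two differentially expressed modules at +1.0 and -1.0 log-CPM,
noise sd 0.5, 6 case vs 6 control samples -- exercises the full pipeline in a
few minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import AnnotationTable, ExpressionMatrix, InteractionNetwork

# scores chosen so both classes survive the default combined-score >= 700 filter
WITHIN_SCORE = 999
BETWEEN_SCORE = 701

DEMO_PARAMS = {
    "n_modules": 6,
    "module_size": 50,
    "p_in": 0.25,
    "p_out": 0.01,
    "de_effects": {1: 1.0, 2: -1.0},
    "noise_sd": 0.5,
    "n_case": 6,
    "n_control": 6,
    # window diameter (2r+1 = 9) kept small relative to the planted module
    # size (50), mirroring the full-scale setting where the window is small
    # relative to the interactome's functional systems
    "radius": 4,
    "alpha": 0.001,
}


@dataclass
class SyntheticTruth:
    """Planted ground truth: module membership and differential effects."""

    module_of: dict                 # gene -> module id (1-based)
    de_effects: dict                # module id -> signed effect (log-CPM units)
    noise_sd: float
    seed: int
    n_case: int = 0
    n_control: int = 0
    baseline: float = 6.0

    @property
    def modules(self) -> list:
        return sorted(set(self.module_of.values()))

    @property
    def de_genes(self) -> set:
        return {g for g, m in self.module_of.items() if m in self.de_effects}

    def module_genes(self, module: int) -> set:
        return {g for g, m in self.module_of.items() if m == module}

    def effect_of(self, gene: str) -> float:
        return self.de_effects.get(self.module_of[gene], 0.0)

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "de_effects": {str(k): v for k, v in self.de_effects.items()},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "baseline": self.baseline,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def gen_network(n_modules: int = 6, module_size: int = 50, p_in: float = 0.25,
                p_out: float = 0.01, seed: int = 0, de_effects=None,
                noise_sd: float = 0.5):
    """Planted-partition graph with module-aligned edge scores.

    Within-module pairs connect with probability ``p_in`` (score 999),
    between-module pairs with ``p_out`` (score 701).
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_modules < 1 or module_size < 1:
        raise ValueError("n_modules and module_size must be positive")
    rng = np.random.default_rng(seed)
    n = n_modules * module_size
    genes = _gene_names(n)
    module = np.repeat(np.arange(1, n_modules + 1), module_size)

    iu, ju = np.triu_indices(n, k=1)
    same = module[iu] == module[ju]
    prob = np.where(same, p_in, p_out)
    keep = rng.random(iu.size) < prob

    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j, s in zip(iu[keep], ju[keep], same[keep]):
        g.add_edge(genes[i], genes[j],
                   score=WITHIN_SCORE if s else BETWEEN_SCORE)

    if de_effects is None:
        de_effects = {m: e for m, e in DEMO_PARAMS["de_effects"].items()
                      if m <= n_modules}
    de_effects = {int(k): float(v) for k, v in de_effects.items()}
    unknown = set(de_effects) - set(range(1, n_modules + 1))
    if unknown:
        raise ValueError(f"DE modules {sorted(unknown)} not among 1..{n_modules}")
    truth = SyntheticTruth(
        module_of={g_: int(m) for g_, m in zip(genes, module)},
        de_effects=de_effects, noise_sd=noise_sd, seed=seed,
    )
    return InteractionNetwork(g), truth


def gen_expression(truth: SyntheticTruth, n_case: int = 6, n_control: int = 6,
                   baseline: float = 6.0, seed: int = 0,
                   baseline_sd: float = 2.0) -> ExpressionMatrix:
    """Case/control log-CPM matrix with planted module-level shifts.

    Per-gene baselines are drawn once (Normal(baseline, baseline_sd));
    samples add Gaussian noise at the truth's sd, and case samples add the
    module's signed effect for genes in DE modules.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per condition")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_of, key=lambda g: (truth.module_of[g], g))
    n_genes = len(genes)
    base = baseline + baseline_sd * rng.standard_normal(n_genes)
    effects = np.array([truth.effect_of(g) for g in genes])

    case = (base[:, None] + effects[:, None]
            + truth.noise_sd * rng.standard_normal((n_genes, n_case)))
    ctrl = (base[:, None]
            + truth.noise_sd * rng.standard_normal((n_genes, n_control)))
    case_names = [f"case_{i + 1}" for i in range(n_case)]
    ctrl_names = [f"ctrl_{i + 1}" for i in range(n_control)]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes,
                          columns=case_names + ctrl_names)
    meta = pd.DataFrame({
        "condition": ["case"] * n_case + ["control"] * n_control,
        "day": 0,
    }, index=pd.Index(case_names + ctrl_names, name="sample"))
    truth.n_case = n_case
    truth.n_control = n_control
    truth.baseline = baseline
    return ExpressionMatrix(values, meta)


def gen_annotation(truth: SyntheticTruth, extra_terms: int = 0,
                   noise_frac: float = 0.0, seed: int = 0) -> AnnotationTable:
    """One term per planted module, plus optional random terms and label noise.

    With ``noise_frac = 1.0`` every annotation is reassigned to a random gene,
    destroying any module alignment (a negative control for enrichment).
    """
    if not 0 <= noise_frac <= 1:
        raise ValueError("noise_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_of)
    rows = [(g, f"M{truth.module_of[g]}") for g in genes]
    module_sizes = [len(truth.module_genes(m)) for m in truth.modules]
    typical = int(np.median(module_sizes)) if module_sizes else 10
    for t in range(extra_terms):
        size = max(2, typical)
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        rows.extend((g, f"X{t + 1}") for g in sorted(members))

    if noise_frac > 0:
        n_noise = int(round(noise_frac * len(rows)))
        idx = rng.choice(len(rows), size=n_noise, replace=False)
        for i in idx:
            rows[i] = (genes[int(rng.integers(0, len(genes)))], rows[i][1])
    df = pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates()
    df["name"] = df["term"].map(
        lambda t: f"module {t[1:]}" if t.startswith("M") else "random term")
    df = df.sort_values(["term", "gene"]).reset_index(drop=True)
    return AnnotationTable(df)


def gen_timecourse(n_groups: int = 3, drift: float = 5.0, seed: int = 0,
                   n_genes: int = 200, samples_per_group: int = 6,
                   noise_sd: float = 0.5):
    """Blocked time course: per-block mean drift over a shared gene program.

    Each gene gets a fixed drift direction; block j shifts it by ``j * drift``
    times that direction, so ``drift = 0`` leaves no block structure.  Returns
    the matrix and the ground-truth block label of each sample.
    """
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    base = 6.0 + 2.0 * rng.standard_normal(n_genes)
    direction = rng.standard_normal(n_genes)
    direction /= np.linalg.norm(direction) / np.sqrt(n_genes)

    cols, labels = [], {}
    data = []
    for j in range(n_groups):
        mean = base + j * drift * direction
        for s in range(samples_per_group):
            name = f"t{j}_s{s + 1}"
            data.append(mean + noise_sd * rng.standard_normal(n_genes))
            cols.append(name)
            labels[name] = j
    values = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    meta = pd.DataFrame({
        "condition": "case",
        "day": [labels[c] * 5 + i % samples_per_group for i, c in enumerate(cols)],
    }, index=pd.Index(cols, name="sample"))
    return ExpressionMatrix(values, meta), labels
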