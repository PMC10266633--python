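"""End-to-end recalibration workflow: fit on well-covered sites, impute the rest.

The central objects follow the fit/results convention of statistical
modelling packages:

* :class:`MethylationImputer` holds the data (a strand-merged methylome and
  its reference genome) and the modelling choices (encoding scheme,
  architecture, low-coverage threshold). Its :meth:`~MethylationImputer.fit`
  selects training sites from the median-Q3 coverage band, builds their
  feature matrices, and trains the network.
* :class:`MethylationImputerResults` carries the trained network and its
  history, and exposes ``predict``, ``impute``, ``evaluate``, ``summary``
  and ``plot_training``.

Only sites at or below the low-coverage threshold are re-estimated; the
observed level passes through everywhere else. Features for imputation are
always built from the observed (low-coverage) methylome itself, never from
any ground truth, including the neighbor chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as ft
from . import io as mio
from . import nn
from .metrics import mae, pearson_r
from .sampling import coverage_quantiles, low_coverage_sites, select_training_sites
from .simulate import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationResult",
    "MethylationImputer",
    "MethylationImputerResults",
    "run_training",
    "impute_low_coverage",
    "evaluate_against_truth",
    "evaluate_external_predictions",
    "compare_feature_sets",
]

MAX_BAD_COLUMNS = 10  # training sites with more N-zeroed sequence columns are dropped


@dataclass
class ImputationResult:
    """Per-site observed vs output levels with provenance flags.

    ``frame`` columns: chrom, pos, coverage, observed_level (nan when the
    site has no reads), output_level, source ("imputed" iff the site was at
    or below the low-coverage threshold, else "observed").
    """

    frame: pd.DataFrame
    threshold: int = 3

    def __post_init__(self) -> None:
        out = self.frame["output_level"].to_numpy()
        if np.any((out < 0) | (out > 1) | ~np.isfinite(out)):
            raise ValueError("output levels must be finite and in [0, 1]")

    @property
    def n_imputed(self) -> int:
        return int((self.frame["source"] == "imputed").sum())

    def write(self, path: str) -> None:
        mio.write_imputed(path, self)

    @classmethod
    def read(cls, path: str, threshold: int = 3) -> "ImputationResult":
        frame = mio.read_imputed(path)
        if len(frame) == 0:
            raise ValueError(f"{path}: empty prediction file")
        return cls(frame=frame, threshold=threshold)


def run_training(
    methylome: mio.Methylome,
    genome: mio.GenomeSequence,
    n_sites: int = 100_000,
    scheme: str = "2mer",
    spec: nn.ModelSpec | None = None,
    config: nn.TrainingConfig | None = None,
    seed: int = 0,
) -> nn.TrainedModel:
    """Select median-Q3 sites, build features, and train the network.

    Targets are the observed levels of the selected (adequately covered)
    sites. The coverage band and all seeds are recorded in the checkpoint
    metadata.
    """
    selection = select_training_sites(methylome, n=n_sites, seed=seed)
    X, n_bad = ft.assemble_features(genome, methylome, selection.sites, scheme=scheme)
    keep = n_bad <= MAX_BAD_COLUMNS
    if not np.all(keep):
        logger.info("dropping %d training sites with N-dominated windows", (~keep).sum())
    sites = [s for s, k in zip(selection.sites, keep) if k]
    X = X[keep]
    y = np.array([
        methylome.get(c, p)[0] / sum(methylome.get(c, p)) for c, p in sites
    ])
    cfg = config or nn.TrainingConfig(seed=seed)
    net = nn.build_model(spec, seed=seed)
    return nn.train(
        net, X, y, cfg, scheme=scheme,
        metadata={
            "coverage_median": selection.median,
            "coverage_q3": selection.q3,
            "n_sites_requested": n_sites,
            "selection_seed": selection.seed,
        },
    )


def impute_low_coverage(
    model: nn.TrainedModel,
    methylome: mio.Methylome,
    genome: mio.GenomeSequence,
    threshold: int = 3,
) -> ImputationResult:
    """Re-estimate every site with coverage <= threshold; pass the rest through."""
    low = set(low_coverage_sites(methylome, threshold=threshold))
    rows = []
    for chrom in methylome.chromosomes:
        pos = methylome.positions(chrom)
        cov = methylome.coverage(chrom)
        lev = methylome.levels(chrom)
        to_impute = [(chrom, int(p)) for p in pos if (chrom, int(p)) in low]
        preds = {}
        if to_impute:
            X, _ = ft.assemble_features(genome, methylome, to_impute, scheme=model.scheme)
            yhat = model.predict(X)
            preds = {site: float(v) for site, v in zip(to_impute, yhat)}
        for i, p in enumerate(pos):
            site = (chrom, int(p))
            if site in preds:
                rows.append((chrom, int(p), int(cov[i]), lev[i], preds[site], "imputed"))
            else:
                rows.append((chrom, int(p), int(cov[i]), lev[i], lev[i], "observed"))
    frame = pd.DataFrame(rows, columns=mio.IMPUTED_COLUMNS)
    return ImputationResult(frame=frame, threshold=threshold)


def _truth_levels(truth, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Reference levels at positions, from a GroundTruth or a deep Methylome."""
    if isinstance(truth, GroundTruth):
        return truth.levels_at(chrom, positions)
    if isinstance(truth, mio.Methylome):
        pos = truth.positions(chrom)
        lev = truth.levels(chrom)
        idx = np.clip(np.searchsorted(pos, positions), 0, max(len(pos) - 1, 0))
        if len(pos) == 0:
            return np.full(len(positions), np.nan)
        return np.where(pos[idx] == positions, lev[idx], np.nan)
    raise TypeError(f"unsupported truth object {type(truth)!r}")


def evaluate_against_truth(
    result: ImputationResult,
    truth,
    original_methylome: mio.Methylome | None = None,
    low_threshold: int = 3,
    min_original_coverage: int = 10,
) -> pd.DataFrame:
    """Per-chromosome and aggregate MAE / Pearson r of raw and output levels.

    Eligible sites are those with a defined observed level at coverage
    <= ``low_threshold`` in the (downsampled) data, coverage
    > ``min_original_coverage`` in the original deep data when one is
    supplied, and a defined reference level. Both the raw observed levels
    and the recalibrated output levels are scored against the reference on
    that same site set, giving comparable error pairs per chromosome.
    """
    rows = []
    pooled: dict[str, list[np.ndarray]] = {"truth": [], "raw": [], "out": []}
    for chrom, grp in result.frame.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(np.int64)
        cov = grp["coverage"].to_numpy(np.int64)
        raw = grp["observed_level"].to_numpy(np.float64)
        out = grp["output_level"].to_numpy(np.float64)
        ref = _truth_levels(truth, chrom, pos)
        elig = (cov <= low_threshold) & np.isfinite(raw) & np.isfinite(ref)
        if original_methylome is not None:
            opos = original_methylome.positions(chrom)
            ocov = original_methylome.coverage(chrom)
            idx = np.clip(np.searchsorted(opos, pos), 0, max(len(opos) - 1, 0))
            deep = (len(opos) > 0) & (opos[idx] == pos) & (ocov[idx] > min_original_coverage)
            elig &= deep
        n = int(elig.sum())
        if n == 0:
            logger.warning("%s: no eligible sites, chromosome omitted", chrom)
            continue
        rows.append({
            "chrom": chrom,
            "n_sites": n,
            "mae_raw": mae(ref[elig], raw[elig]),
            "mae_output": mae(ref[elig], out[elig]),
            "r_raw": pearson_r(ref[elig], raw[elig]) if n > 1 else np.nan,
            "r_output": pearson_r(ref[elig], out[elig]) if n > 1 else np.nan,
        })
        pooled["truth"].append(ref[elig])
        pooled["raw"].append(raw[elig])
        pooled["out"].append(out[elig])
    if not rows:
        raise ValueError("no chromosome had eligible sites")
    t = np.concatenate(pooled["truth"])
    r = np.concatenate(pooled["raw"])
    o = np.concatenate(pooled["out"])
    rows.append({
        "chrom": "all",
        "n_sites": len(t),
        "mae_raw": mae(t, r),
        "mae_output": mae(t, o),
        "r_raw": pearson_r(t, r) if len(t) > 1 else np.nan,
        "r_output": pearson_r(t, o) if len(t) > 1 else np.nan,
    })
    return pd.DataFrame(rows)


def evaluate_external_predictions(
    prediction_file: str,
    truth,
    original_methylome: mio.Methylome | None = None,
    low_threshold: int = 3,
    min_original_coverage: int = 10,
) -> pd.DataFrame:
    """Score any tool's predictions written in the imputation TSV schema."""
    result = ImputationResult.read(prediction_file, threshold=low_threshold)
    return evaluate_against_truth(
        result, truth, original_methylome,
        low_threshold=low_threshold,
        min_original_coverage=min_original_coverage,
    )


def compare_feature_sets(
    methylome: mio.Methylome,
    genome: mio.GenomeSequence,
    n_train: int = 2000,
    n_test: int = 1000,
    spec: nn.ModelSpec | None = None,
    config: nn.TrainingConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """MAE of four predictors on held-out well-covered sites.

    Trains the network with chain-only, chain+one-hot and chain+2-mer
    inputs on the same training split, and scores them together with the
    untrained neighbor-average baseline on a disjoint test set drawn from
    the same median-Q3 coverage band. Chain-only uses the standard input
    with the four sequence rows zeroed.
    """
    selection = select_training_sites(methylome, n=n_train + n_test, seed=seed)
    if len(selection.sites) < n_train + n_test:
        n_train = int(0.67 * len(selection.sites))
        n_test = len(selection.sites) - n_train
        logger.warning("fewer eligible sites than requested; using %d/%d", n_train, n_test)
    order = np.random.default_rng(np.random.SeedSequence([seed, 7])).permutation(
        len(selection.sites)
    )
    train_sites = [selection.sites[i] for i in order[:n_train]]
    test_sites = [selection.sites[i] for i in order[n_train : n_train + n_test]]

    def observed(sites):
        return np.array([
            methylome.get(c, p)[0] / sum(methylome.get(c, p)) for c, p in sites
        ])

    y_tr, y_te = observed(train_sites), observed(test_sites)
    cfg = config or nn.TrainingConfig(seed=seed)
    rows = []
    X2_tr, _ = ft.assemble_features(genome, methylome, train_sites, scheme="2mer")
    X2_te, _ = ft.assemble_features(genome, methylome, test_sites, scheme="2mer")
    X1_tr, _ = ft.assemble_features(genome, methylome, train_sites, scheme="onehot")
    X1_te, _ = ft.assemble_features(genome, methylome, test_sites, scheme="onehot")
    Xc_tr, Xc_te = X2_tr.copy(), X2_te.copy()
    Xc_tr[:, :4] = 0.0
    Xc_te[:, :4] = 0.0
    for name, (Xtr, Xte) in {
        "chain_only": (Xc_tr, Xc_te),
        "chain+onehot": (X1_tr, X1_te),
        "chain+2mer": (X2_tr, X2_te),
    }.items():
        net = nn.build_model(spec, seed=seed)
        trained = nn.train(net, Xtr, y_tr, cfg, scheme=name)
        rows.append({
            "feature_set": name,
            "mae": mae(y_te, trained.predict(Xte)),
            "n_test": len(y_te),
            "epochs": len(trained.history),
        })
    baseline = np.array([ft.neighbor_average(x[4, :, 0]) for x in X2_te])
    rows.append({
        "feature_set": "neighbor_average",
        "mae": mae(y_te, baseline),
        "n_test": len(y_te),
        "epochs": 0,
    })
    return pd.DataFrame(rows)


class MethylationImputer:
    """Recalibration model over a methylome and its reference genome.

    Parameters
    ----------
    methylome
        Strand-merged per-CpG read counts (the data to recalibrate).
    genome
        Reference sequence the methylome is mapped to.
    scheme
        Sequence encoding, "2mer" (default) or "onehot".
    low_coverage_threshold
        Sites with at most this many reads are re-estimated at imputation
        time (default 3).
    spec
        Network architecture; defaults to the standard 128-filter layout.
    """

    def __init__(
        self,
        methylome: mio.Methylome,
        genome: mio.GenomeSequence,
        scheme: str = "2mer",
        low_coverage_threshold: int = 3,
        spec: nn.ModelSpec | None = None,
    ):
        self.methylome = methylome
        self.genome = genome
        self.scheme = scheme
        self.low_coverage_threshold = low_coverage_threshold
        self.spec = spec or nn.ModelSpec()

    @classmethod
    def from_files(
        cls,
        report_path: str,
        fasta_path: str,
        merge_replicate_path: str | None = None,
        **kwargs,
    ) -> "MethylationImputer":
        """Build from a Bismark CpG report and a FASTA reference."""
        genome = mio.GenomeSequence.from_fasta(fasta_path)
        methylome = mio.merge_strands(mio.read_cpg_report(report_path))
        if merge_replicate_path is not None:
            rep2 = mio.merge_strands(mio.read_cpg_report(merge_replicate_path))
            methylome = mio.merge_replicates(methylome, rep2)
        return cls(methylome, genome, **kwargs)

    def fit(
        self,
        n_sites: int = 100_000,
        config: nn.TrainingConfig | None = None,
        seed: int = 0,
    ) -> "MethylationImputerResults":
        """Train the network on median-Q3 coverage sites and return results."""
        trained = run_training(
            self.methylome, self.genome,
            n_sites=n_sites, scheme=self.scheme, spec=self.spec,
            config=config, seed=seed,
        )
        return MethylationImputerResults(self, trained)


class MethylationImputerResults:
    """Fitted recalibration model: trained network, history, and imputation."""

    def __init__(self, model: MethylationImputer, trained: nn.TrainedModel):
        self.model = model
        self.trained_model = trained

    @property
    def history(self) -> pd.DataFrame:
        return self.trained_model.history

    def predict(self, sites: list[tuple[str, int]]) -> np.ndarray:
        """Predicted levels for arbitrary CpG sites of the model's genome."""
        X, _ = ft.assemble_features(
            self.model.genome, self.model.methylome, sites,
            scheme=self.trained_model.scheme,
        )
        return self.trained_model.predict(X)

    def impute(
        self,
        methylome: mio.Methylome | None = None,
        threshold: int | None = None,
    ) -> ImputationResult:
        """Re-estimate low-coverage sites of ``methylome`` (default: the fitted one)."""
        return impute_low_coverage(
            self.trained_model,
            methylome if methylome is not None else self.model.methylome,
            self.model.genome,
            threshold=threshold if threshold is not None else self.model.low_coverage_threshold,
        )

    def evaluate(self, truth, original_methylome=None, **kwargs) -> pd.DataFrame:
        """Impute, then score raw vs recalibrated levels against a reference."""
        return evaluate_against_truth(
            self.impute(), truth, original_methylome,
            low_threshold=self.model.low_coverage_threshold, **kwargs,
        )

    def summary(self) -> str:
        t = self.trained_model
        meta = t.metadata
        trace = " -> ".join(
            f"{name}{list(shape)}" for name, shape in t.spec.shape_trace()
        )
        last = t.history.iloc[-1] if len(t.history) else None
        lines = [
            "Methylation recalibration model",
            "=" * 64,
            f"Encoding scheme:        {t.scheme}",
            f"Architecture:           {trace}",
            f"Training sites:         {meta.get('n_train', '?')} "
            f"(+{meta.get('n_val', '?')} validation)",
            f"Coverage band:          [{meta.get('coverage_median', '?')}, "
            f"{meta.get('coverage_q3', '?')}] reads",
            f"Epochs run:             {len(t.history)} "
            f"(best epoch {meta.get('best_epoch', '?')})",
            f"Best validation MAE:    {meta.get('best_val_mae', float('nan')):.4f}",
        ]
        if last is not None:
            lines.append(
                f"Final epoch MSE/MAE:    train {last['train_mse']:.4f}/"
                f"{last['train_mae']:.4f}, val {last['val_mse']:.4f}/{last['val_mae']:.4f}"
            )
        lines.append(f"Low-coverage threshold: <= {self.model.low_coverage_threshold} reads")
        return "\n".join(lines)

    def plot_training(self, path: str | None = None):
        """Per-epoch MSE and MAE curves for the train and validation splits."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        h = self.history
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, metric in zip(axes, ("mse", "mae")):
            ax.plot(h["epoch"], h[f"train_{metric}"], label="train")
            ax.plot(h["epoch"], h[f"val_{metric}"], label="validation")
            ax.set_xlabel("epoch")
            ax.set_ylabel(metric.upper())
            ax.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def save(self, path: str) -> None:
        self.trained_model.save(path)
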