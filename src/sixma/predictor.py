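"""High-level model interface: build from sequences, fit, inspect results.

:class:`Site6mAModel` bundles the full training protocol — encode with NPS
and PseDNC, fuse, rank by ANOVA F, sweep nested feature subsets, grid-search
the RBF-SVM and cross-validate — behind a fit() call that returns a
:class:`Site6mAResults` carrying the selection curve, the tuned model, the
cross-validated metrics and plotting/prediction helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, SelectionResult, fuse, incremental_select
from .io import SequenceRecord, read_labeled_fasta, validate_records
from .nps import NPSConfig, encode_nps_matrix
from .psednc import PseDNCConfig, encode_psednc_matrix
from .svm import (
    EvaluationReport,
    ModelBundle,
    cross_validate,
    grid_search_train,
    predict as _predict,
)

__all__ = ["Site6mAModel", "Site6mAResults", "encode_records"]


def encode_records(
    records: Sequence[SequenceRecord],
    nps_cfg: NPSConfig = NPSConfig(),
    psednc_cfg: PseDNCConfig = PseDNCConfig(),
) -> FeatureMatrix:
    """Fused NPS + PseDNC feature matrix (522 columns at defaults)."""
    validate_records(records, width=nps_cfg.width)
    return fuse(
        [encode_nps_matrix(records, nps_cfg), encode_psednc_matrix(records, psednc_cfg)],
        prefixes=["nps", "psednc"],
    )


class Site6mAModel:
    """A 6mA site prediction model over a fused feature matrix.

    Construct from a ready :class:`FeatureMatrix`, or from sequence records /
    FASTA files via the ``from_*`` constructors (which run both encoders and
    fuse them).  Call :meth:`fit` to run selection, hyperparameter tuning and
    cross-validated evaluation.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        nps_cfg: NPSConfig = NPSConfig(),
        psednc_cfg: PseDNCConfig = PseDNCConfig(),
    ):
        if features.labels is None:
            raise ValueError("training requires labeled features")
        self.features = features
        self.nps_cfg = nps_cfg
        self.psednc_cfg = psednc_cfg

    @classmethod
    def from_records(
        cls,
        records: Sequence[SequenceRecord],
        nps_cfg: NPSConfig = NPSConfig(),
        psednc_cfg: PseDNCConfig = PseDNCConfig(),
    ) -> "Site6mAModel":
        return cls(encode_records(records, nps_cfg, psednc_cfg), nps_cfg, psednc_cfg)

    @classmethod
    def from_fasta(
        cls,
        positives: str | Path,
        negatives: str | Path,
        nps_cfg: NPSConfig = NPSConfig(),
        psednc_cfg: PseDNCConfig = PseDNCConfig(),
    ) -> "Site6mAModel":
        return cls.from_records(read_labeled_fasta(positives, negatives), nps_cfg, psednc_cfg)

    def fit(
        self,
        select: bool = True,
        dims: Optional[Iterable[int]] = None,
        selection_folds: int = 5,
        selection_mode: str = "paper",
        grid: Optional[dict] = None,
        grid_folds: int = 5,
        cv_folds: int = 10,
        repeats: int = 1,
        seed: int = 0,
    ) -> "Site6mAResults":
        """Run selection -> grid search -> cross-validation -> final refit.

        ``select=False`` keeps all features.  ``dims`` restricts the subset
        sizes swept during selection (default: every dimension).  The final
        model is refit on all data with the tuned (cost, gamma).
        """
        M = self.features
        selection: Optional[SelectionResult] = None
        idx: Optional[np.ndarray] = None
        if select:
            selection = incremental_select(
                M, seed=seed, dims=dims, folds=selection_folds, mode=selection_mode
            )
            idx = selection.selected_indices
        bundle = grid_search_train(
            M, grid=grid, folds=grid_folds, seed=seed, selected_indices=idx
        )
        report = cross_validate(
            M,
            n=cv_folds,
            seed=seed,
            repeats=repeats,
            cost=bundle.cost,
            gamma=bundle.gamma,
            selected_indices=idx,
        )
        return Site6mAResults(model=self, bundle=bundle, selection=selection, report=report, seed=seed)


@dataclass
class Site6mAResults:
    """Fitted-model results: tuned classifier, selection curve, CV metrics."""

    model: Site6mAModel
    bundle: ModelBundle
    selection: Optional[SelectionResult]
    report: EvaluationReport
    seed: int

    @property
    def mean_metrics(self) -> dict[str, float]:
        return self.report.mean_metrics

    @property
    def optimal_dim(self) -> Optional[int]:
        return None if self.selection is None else self.selection.optimal_dim

    def predict(self, records: Sequence[SequenceRecord]) -> pd.DataFrame:
        """Score new windows: id, 6mA probability, binary call (p > 0.5)."""
        M = encode_records(records, self.model.nps_cfg, self.model.psednc_cfg)
        return _predict(self.bundle, M)

    def summary(self) -> str:
        lines = ["6mA site prediction model", "=" * 46]
        lines.append(f"  samples                    {self.model.features.n_samples}")
        lines.append(f"  fused features             {self.model.features.n_features}")
        if self.selection is not None:
            lines.append(f"  selected features          {self.selection.optimal_dim}")
        lines.append(f"  kernel                     {self.bundle.kernel}")
        lines.append(f"  cost (C)                   {self.bundle.cost:g}")
        lines.append(f"  gamma                      {self.bundle.gamma}")
        lines.append("")
        lines.append(self.report.summary())
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write model bundle, selection result and evaluation report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.bundle.save(outdir / "model")
        if self.selection is not None:
            self.selection.to_json(outdir / "selection.json")
            self.selection.curve_to_tsv(outdir / "accuracy_curve.tsv")
        self.report.to_json(outdir / "evaluation.json")
        self.report.roc_to_tsv(outdir / "roc.tsv")

    def plot_roc(self, ax=None):
        """Pooled cross-validated ROC curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.report.roc_points[:, 0], self.report.roc_points[:, 1],
                label=f"AUC = {self.mean_metrics['AUC']:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax

    def plot_accuracy_curve(self, ax=None):
        """Accuracy versus feature-subset dimension from the selection sweep."""
        import matplotlib.pyplot as plt

        if self.selection is None:
            raise ValueError("model was fitted without feature selection")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.selection.dims, self.selection.accuracy_curve)
        ax.axvline(self.selection.optimal_dim, color="r", ls=":",
                   label=f"optimal dimension = {self.selection.optimal_dim}")
        ax.set_xlabel("Feature subset dimension")
        ax.set_ylabel("CV accuracy")
        ax.legend()
        return ax
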