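"""Expert judge panel: majority-vote consensus and interrater agreement.

Severity labels (mild / severe) come from a panel of expert raters; a simple
majority is determinative, and participants on whom any judge disagreed are
flagged because downstream learning curves degrade when they enter the
cohort.  Agreement is summarized with Fleiss' kappa over the panel plus the
pairwise Cohen's kappa matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

CLASSES = ("mild", "severe")


@dataclass
class JudgePanel:
    """Per-participant class calls from multiple raters.

    ``calls`` is participants × judges with entries "mild"/"severe";
    ``consensus`` and ``disagreement`` are populated by
    :func:`majority_vote`.
    """

    calls: pd.DataFrame
    consensus: pd.Series | None = field(default=None)
    disagreement: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        bad = set(self.calls.to_numpy().ravel()) - set(CLASSES)
        if bad:
            raise ValueError(f"judge calls must be in {CLASSES}, got {sorted(bad)}")
        if self.calls.shape[1] < 1:
            raise ValueError("panel needs at least one judge")

    @property
    def n_judges(self) -> int:
        return self.calls.shape[1]

    def to_csv(self, path) -> None:
        self.calls.to_csv(path, index_label="participant_id")

    @classmethod
    def from_csv(cls, path) -> "JudgePanel":
        return cls(pd.read_csv(path, index_col="participant_id"))


def majority_vote(panel: JudgePanel) -> JudgePanel:
    """Resolve consensus labels by simple majority; flag any disagreement.

    Raises ``ValueError`` on an exact tie (possible only with an even judge
    count): convene an odd panel or supply an explicit tie-break policy.
    """
    n_severe = (panel.calls == "severe").sum(axis=1)
    n_total = panel.calls.shape[1]
    ties = n_severe * 2 == n_total
    if ties.any():
        tied = list(panel.calls.index[ties])
        raise ValueError(
            f"tied votes for participants {tied}: use an odd number of judges "
            "or resolve ties externally"
        )
    consensus = pd.Series(
        np.where(n_severe * 2 > n_total, "severe", "mild"), index=panel.calls.index
    )
    disagreement = (panel.calls.nunique(axis=1) > 1).astype(bool)
    return JudgePanel(panel.calls.copy(), consensus, disagreement)


@dataclass
class AgreementReport:
    fleiss_kappa: float                 # NaN when undefined (single category)
    pairwise_cohen: pd.DataFrame        # judges × judges, diagonal 1
    undefined: bool = False


def interrater_agreement(panel: JudgePanel) -> AgreementReport:
    """Fleiss' kappa over the panel and the pairwise Cohen's kappa matrix.

    When every judge uses a single category for every participant, chance
    agreement equals observed agreement and kappa is undefined; this is
    reported as NaN with ``undefined=True`` rather than an arbitrary value.
    """
    if panel.n_judges < 2:
        raise ValueError("agreement needs at least two judges")
    codes = (panel.calls == "severe").astype(int).to_numpy()
    single_category = len(np.unique(codes)) < 2
    if single_category:
        fk = float("nan")
    else:
        counts, _ = aggregate_raters(codes, n_cat=2)
        fk = float(fleiss_kappa(counts))
    judges = list(panel.calls.columns)
    mat = pd.DataFrame(np.eye(len(judges)), index=judges, columns=judges)
    for i, a in enumerate(judges):
        for b in judges[i + 1 :]:
            if single_category:
                ck = float("nan")
            else:
                ck = float(cohen_kappa_score(codes[:, i], codes[:, judges.index(b)]))
            mat.at[a, b] = mat.at[b, a] = ck
    if single_category:
        np.fill_diagonal(mat.to_numpy(), float("nan"))
        mat = pd.DataFrame(np.full((len(judges),) * 2, np.nan), index=judges, columns=judges)
    return AgreementReport(fleiss_kappa=fk, pairwise_cohen=mat, undefined=single_category)
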