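"""Factor extraction from the variable correlation matrix.

Principal-component extraction, unrotated: eigendecompose the correlation
matrix of the standardized variables, scale eigenvectors by the square
root of their eigenvalues to obtain loadings, and project the
standardized data on the unit eigenvectors to obtain country scores.
Variance explained by factor j is ``100 * lambda_j / p``.  A deterministic
sign convention (the largest-|loading| entry of each factor is positive)
makes output stable across runs and linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CountryPanel, PanelError


@dataclass
class FactorSolution:
    loadings: pd.DataFrame          # variables x k, |loading| <= 1
    variance_explained: np.ndarray  # k percentages, non-increasing
    scores: pd.DataFrame            # countries x k, mean 0, var = eigenvalue
    eigenvalues: np.ndarray         # full scree (all p eigenvalues, desc)


def fit_factors(panel: CountryPanel, variables: list[str] | None = None,
                k: int = 3, missing: str = "impute_mean") -> FactorSolution:
    """Extract ``k`` factors from the correlation matrix of ``variables``.

    Missing values are mean-imputed per variable by default (``missing=
    "listwise"`` drops incomplete countries instead; with dozens of
    variables and few countries that often leaves too few rows).
    """
    if variables is None:
        variables = panel.variables
    if k < 1:
        raise PanelError("k must be >= 1")
    if k > len(variables):
        raise PanelError(f"k={k} exceeds number of variables {len(variables)}")
    data = panel.values[list(variables)]
    if missing == "listwise":
        data = data.dropna()
    elif missing == "impute_mean":
        data = data.fillna(data.mean())
    else:
        raise PanelError(f"unknown missing policy {missing!r}")
    if len(data) < 3:
        raise PanelError(f"need >= 3 complete countries, got {len(data)}")
    sd = data.std(ddof=1)
    const = sd.index[sd == 0].tolist()
    if const:
        raise PanelError(f"constant variables cannot be standardized: {const}")
    z = (data - data.mean()) / sd
    corr = (z.to_numpy().T @ z.to_numpy()) / (len(z) - 1)

    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-8 * max(evals[0], 1.0)
    if evals[-1] < -tol:
        raise PanelError(f"correlation matrix not PSD (min eigenvalue {evals[-1]:.3g})")
    evals = np.clip(evals, 0.0, None)
    if k > np.sum(evals > tol):
        raise PanelError(f"k={k} exceeds numerical rank {int(np.sum(evals > tol))}")

    vecs = evecs[:, :k].copy()
    # deterministic sign: flip so the largest-|loading| entry is positive
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    loadings = vecs * np.sqrt(evals[:k])
    scores = z.to_numpy() @ vecs

    factor_names = [f"factor{j + 1}" for j in range(k)]
    p = len(variables)
    return FactorSolution(
        loadings=pd.DataFrame(loadings, index=list(variables), columns=factor_names),
        variance_explained=100.0 * evals[:k] / p,
        scores=pd.DataFrame(scores, index=data.index, columns=factor_names),
        eigenvalues=evals,
    )


def plot_plane(solution: FactorSolution, axes: tuple[int, int] = (1, 2),
               mode: str = "loadings", figure_path=None):
    """Coordinates of variables or countries on a pair of factor axes.

    Returns ``(coords, combined_variance)``: a (name, x, y) table and the
    summed variance percentage of the two axes — the "explaining X%
    variability" label of a factor-plane plot.  ``figure_path`` optionally
    writes a scatter via matplotlib.
    """
    a, b = axes
    k = solution.loadings.shape[1]
    if not (1 <= a <= k and 1 <= b <= k) or a == b:
        raise PanelError(f"axes {axes} invalid for a {k}-factor solution")
    table = {"loadings": solution.loadings, "scores": solution.scores}.get(mode)
    if table is None:
        raise PanelError(f"unknown mode {mode!r}")
    coords = pd.DataFrame({
        "name": table.index,
        "x": table.iloc[:, a - 1].to_numpy(),
        "y": table.iloc[:, b - 1].to_numpy(),
    })
    combined = float(solution.variance_explained[a - 1]
                     + solution.variance_explained[b - 1])
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 8))
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axvline(0, color="0.8", lw=0.8)
        ax.scatter(coords["x"], coords["y"], s=12)
        for _, row in coords.iterrows():
            ax.annotate(str(row["name"]), (row["x"], row["y"]), fontsize=6)
        ax.set_xlabel(f"Factor {a} ({solution.variance_explained[a - 1]:.1f}%)")
        ax.set_ylabel(f"Factor {b} ({solution.variance_explained[b - 1]:.1f}%)")
        ax.set_title(f"{mode}: factors {a} and {b} "
                     f"(explaining {combined:.1f}% variability)")
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return coords, combined
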