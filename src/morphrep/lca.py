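"""Morph detection: multinomial latent-class mixtures over gesture modifiers.

For each gesture action with enough observations, the modifier vectors are
fit with a k-class mixture of independent multinomials by EM; the number of
classes is chosen by BIC (ties to the smaller k); classes surviving the
minimum-observation rule become morphs, labelled ``"<Action>.<i>_<K>"`` with
``i`` ordered by descending size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .vocab import MODIFIERS, UNCLEAR, ModifierVocabulary

DEFAULT_ACTION_MIN = 10
DEFAULT_MORPH_MIN = 5
DEFAULT_K_MAX = 8
DEFAULT_RESTARTS = 20
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000

_LOG_FLOOR = 1e-300


class ReduceKError(ValueError):
    """Requested more classes than there are distinct modifier vectors."""


@dataclass
class ActionVectors:
    """Encoded modifier vectors of one gesture action, ready for the fit."""

    gesture_action: str
    matrix: np.ndarray  # (n_obs, n_modifiers) integer level codes
    modifiers: tuple[str, ...]  # columns, after dropping invariant modifiers
    level_labels: tuple[tuple[str, ...], ...]  # per column
    token_ids: tuple[str, ...]
    constant_modifiers: dict[str, str]  # dropped invariant modifiers and their level

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(len(l) for l in self.level_labels)


@dataclass
class ExclusionReport:
    """Token accounting for the latent-class filter stage."""

    n_input: int
    n_unclear: int
    unspecified_actions: dict[str, int]  # action -> remaining tokens (< action_min)
    dropped_invariant: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_unspecified_tokens(self) -> int:
        return sum(self.unspecified_actions.values())

    @property
    def n_analyzed(self) -> int:
        return self.n_input - self.n_unclear - self.n_unspecified_tokens


def prepare_lca_inputs(
    tokens: pd.DataFrame,
    vocab: ModifierVocabulary,
    action_min: int = DEFAULT_ACTION_MIN,
) -> tuple[dict[str, ActionVectors], ExclusionReport]:
    """Per-action modifier vectors after the unclear and sample-size filters.

    Tokens with an unclear level on any applicable modifier are removed;
    actions left with fewer than ``action_min`` tokens are routed to the
    "unspecified" list; modifiers invariant within an action are dropped from
    its vectors (they contribute a constant likelihood factor).
    """
    report = ExclusionReport(n_input=len(tokens), n_unclear=0, unspecified_actions={})
    vectors: dict[str, ActionVectors] = {}
    for action, group in tokens.groupby("gesture_action", sort=True):
        applicable = vocab.applicable_modifiers(action)
        clear_mask = np.ones(len(group), dtype=bool)
        for modifier in applicable:
            clear_mask &= group[modifier].to_numpy() != UNCLEAR
        report.n_unclear += int((~clear_mask).sum())
        clear = group[clear_mask]
        if len(clear) < action_min:
            report.unspecified_actions[str(action)] = len(clear)
            continue
        columns: list[str] = []
        codes: list[np.ndarray] = []
        labels: list[tuple[str, ...]] = []
        constants: dict[str, str] = {}
        for modifier in MODIFIERS:
            if modifier not in applicable:
                continue
            values = clear[modifier]
            uniques = sorted(values.unique())
            if len(uniques) == 1:
                constants[modifier] = uniques[0]
                continue
            lookup = {level: i for i, level in enumerate(uniques)}
            columns.append(modifier)
            codes.append(values.map(lookup).to_numpy(dtype=int))
            labels.append(tuple(uniques))
        matrix = (
            np.column_stack(codes) if codes else np.empty((len(clear), 0), dtype=int)
        )
        if constants:
            report.dropped_invariant[str(action)] = tuple(sorted(constants))
        vectors[str(action)] = ActionVectors(
            gesture_action=str(action),
            matrix=matrix,
            modifiers=tuple(columns),
            level_labels=tuple(labels),
            token_ids=tuple(clear["token_id"]),
            constant_modifiers=constants,
        )
    return vectors, report


@dataclass
class LcaModel:
    gesture_action: str
    k: int
    class_weights: np.ndarray  # (k,)
    item_response: tuple[np.ndarray, ...]  # per modifier: (k, L_m)
    log_likelihood: float
    bic: float
    n_obs: int
    n_parameters: int
    assignments: np.ndarray  # (n_obs,) argmax-posterior class index
    posterior_margin: np.ndarray  # (n_obs,) top1 - top2 posterior
    modifiers: tuple[str, ...]
    level_labels: tuple[tuple[str, ...], ...]
    token_ids: tuple[str, ...]
    ll_history: np.ndarray  # best restart's log-likelihood trace
    converged: bool


def _log_components(
    matrix: np.ndarray,
    weights: np.ndarray,
    item_response: Sequence[np.ndarray],
) -> np.ndarray:
    """(n, k) array of log pi_k + sum_m log p_{k,m,x_im}."""
    n = matrix.shape[0]
    k = len(weights)
    out = np.broadcast_to(
        np.log(np.maximum(weights, _LOG_FLOOR)), (n, k)
    ).copy()
    for m, p in enumerate(item_response):
        out += np.log(np.maximum(p[:, matrix[:, m]], _LOG_FLOOR)).T
    return out


def _em_once(
    matrix: np.ndarray,
    row_weights: np.ndarray,
    n_levels: Sequence[int],
    weights: np.ndarray,
    item_response: list[np.ndarray],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[np.ndarray], float, list[float], bool]:
    n_total = row_weights.sum()
    history: list[float] = []
    converged = False
    previous = -np.inf
    for _ in range(max_iter):
        scores = _log_components(matrix, weights, item_response)
        top = scores.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            log_norm = top[:, 0] + np.log(np.exp(scores - top).sum(axis=1))
        ll = float((row_weights * log_norm).sum())
        history.append(ll)
        responsibilities = np.exp(scores - log_norm[:, None])
        weighted = responsibilities * row_weights[:, None]
        class_mass = weighted.sum(axis=0)
        weights = class_mass / n_total
        item_response = []
        for m, levels in enumerate(n_levels):
            counts = np.zeros((len(weights), levels))
            np.add.at(counts.T, matrix[:, m], weighted)
            denom = np.maximum(class_mass[:, None], _LOG_FLOOR)
            item_response.append(counts / denom)
        if previous > -np.inf and ll - previous <= tol * max(1.0, abs(ll)):
            converged = True
            break
        previous = ll
    return weights, item_response, history[-1], history, converged


def _deterministic_init(
    unique_rows: np.ndarray,
    row_weights: np.ndarray,
    n_levels: Sequence[int],
    k: int,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Seed classes at the k most frequent distinct vectors."""
    order = np.lexsort(tuple(unique_rows.T) + (-row_weights,))
    prototypes = unique_rows[order[:k]]
    weights = np.full(k, 1.0 / k)
    item_response = []
    for m, levels in enumerate(n_levels):
        p = np.full((k, levels), 0.1 / max(levels - 1, 1))
        p[np.arange(k), prototypes[:, m]] = 0.9
        p /= p.sum(axis=1, keepdims=True)
        item_response.append(p)
    return weights, item_response


def fit_lca(
    vectors: ActionVectors,
    k: int,
    n_restarts: int = DEFAULT_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
) -> LcaModel:
    """Fit a k-class multinomial mixture by EM, best of ``n_restarts``.

    The first restart is a deterministic initialisation at the k most
    frequent distinct vectors; the rest are Dirichlet-random.  The EM runs on
    the distinct-vector compression of the data, so cost scales with the
    number of distinct modifier vectors rather than tokens.
    """
    matrix = vectors.matrix
    n, n_mod = matrix.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("need at least k observations")
    unique_rows, inverse, counts = np.unique(
        matrix, axis=0, return_inverse=True, return_counts=True
    )
    if k > len(unique_rows):
        raise ReduceKError(
            f"{vectors.gesture_action}: k={k} exceeds {len(unique_rows)} distinct vectors"
        )
    n_levels = vectors.n_levels
    row_weights = counts.astype(float)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, list[np.ndarray], list[float], bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            weights, item_response = _deterministic_init(
                unique_rows, row_weights, n_levels, k
            )
        else:
            weights = rng.dirichlet(np.ones(k))
            item_response = [rng.dirichlet(np.ones(levels), size=k) for levels in n_levels]
        weights, item_response, ll, history, converged = _em_once(
            unique_rows, row_weights, n_levels, weights, item_response, tol, max_iter
        )
        if best is None or ll > best[0]:
            best = (ll, weights, item_response, history, converged)
    assert best is not None
    ll, weights, item_response, history, converged = best

    scores = _log_components(unique_rows, weights, item_response)
    top = scores.max(axis=1, keepdims=True)
    log_norm = top[:, 0] + np.log(np.exp(scores - top).sum(axis=1))
    posteriors = np.exp(scores - log_norm[:, None])
    # ties broken toward the lower class index (argmax does exactly that)
    unique_assignments = posteriors.argmax(axis=1)
    if k > 1:
        part = np.partition(posteriors, k - 2, axis=1)
        margins = part[:, -1] - part[:, -2]
    else:
        margins = np.ones(len(unique_rows))
    n_parameters = (k - 1) + k * sum(levels - 1 for levels in n_levels)
    bic = -2.0 * ll + n_parameters * np.log(n)
    return LcaModel(
        gesture_action=vectors.gesture_action,
        k=k,
        class_weights=weights,
        item_response=tuple(item_response),
        log_likelihood=ll,
        bic=float(bic),
        n_obs=n,
        n_parameters=n_parameters,
        assignments=unique_assignments[inverse],
        posterior_margin=margins[inverse],
        modifiers=vectors.modifiers,
        level_labels=vectors.level_labels,
        token_ids=vectors.token_ids,
        ll_history=np.asarray(history),
        converged=converged,
    )


def select_model(
    vectors: ActionVectors,
    k_max: int = DEFAULT_K_MAX,
    n_restarts: int = DEFAULT_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
) -> LcaModel:
    """Fit k = 1..min(k_max, distinct vectors) and return the minimum-BIC
    model; BIC ties go to the smaller k."""
    n_distinct = len(np.unique(vectors.matrix, axis=0))
    sequence = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = sequence.spawn(min(k_max, n_distinct))
    best: LcaModel | None = None
    for k in range(1, min(k_max, n_distinct) + 1):
        model = fit_lca(
            vectors,
            k,
            n_restarts=n_restarts,
            tol=tol,
            max_iter=max_iter,
            seed=seeds[k - 1],
        )
        if best is None or model.bic < best.bic:
            best = model
    assert best is not None
    return best


@dataclass
class Morph:
    morph_id: str
    gesture_action: str
    index: int  # 1-based, ordered by descending size
    token_count: int
    modal_configuration: dict[str, str]
    token_ids: tuple[str, ...]


def derive_morphs(
    model: LcaModel,
    morph_min: int = DEFAULT_MORPH_MIN,
    constant_modifiers: Mapping[str, str] | None = None,
) -> tuple[list[Morph], list[str]]:
    """Hard-assign tokens and keep classes with >= ``morph_min`` members.

    Surviving classes are renumbered by descending size (ties by original
    class index) as ``"<Action>.<i>_<K>"``; tokens of dropped classes are
    returned as unassigned.
    """
    sizes = np.bincount(model.assignments, minlength=model.k)
    surviving = [c for c in range(model.k) if sizes[c] >= morph_min]
    surviving.sort(key=lambda c: (-sizes[c], c))
    total = len(surviving)
    token_ids = np.asarray(model.token_ids)
    morphs: list[Morph] = []
    for rank, class_idx in enumerate(surviving, start=1):
        mask = model.assignments == class_idx
        modal = dict(constant_modifiers or {})
        for m, modifier in enumerate(model.modifiers):
            level_idx = int(model.item_response[m][class_idx].argmax())
            modal[modifier] = model.level_labels[m][level_idx]
        morphs.append(
            Morph(
                morph_id=f"{model.gesture_action}.{rank}_{total}",
                gesture_action=model.gesture_action,
                index=rank,
                token_count=int(sizes[class_idx]),
                modal_configuration=modal,
                token_ids=tuple(token_ids[mask]),
            )
        )
    unassigned_mask = ~np.isin(model.assignments, surviving)
    return morphs, list(token_ids[unassigned_mask])


@dataclass
class ActionResult:
    gesture_action: str
    model: LcaModel
    morphs: list[Morph]
    unassigned_token_ids: list[str]


@dataclass
class MorphRepertoire:
    unimorphic: list[str]
    polymorphic: dict[str, list[Morph]]
    unspecified: list[str]
    zero_morph: list[str]  # analyzed actions where every class fell below morph_min
    n_unassigned: int
    n_analyzed_tokens: int

    @property
    def n_units(self) -> int:
        return (
            len(self.unimorphic)
            + sum(len(m) for m in self.polymorphic.values())
            + len(self.unspecified)
        )

    @property
    def unassigned_fraction(self) -> float:
        return self.n_unassigned / self.n_analyzed_tokens if self.n_analyzed_tokens else 0.0


def summarize_morph_repertoire(
    results: Iterable[ActionResult],
    unspecified_actions: Iterable[str],
) -> tuple[MorphRepertoire, dict]:
    """Partition actions into unimorphic / polymorphic / unspecified and
    compute the morph summary statistics."""
    unimorphic: list[str] = []
    polymorphic: dict[str, list[Morph]] = {}
    zero_morph: list[str] = []
    n_unassigned = 0
    n_tokens = 0
    for result in results:
        n_unassigned += len(result.unassigned_token_ids)
        n_tokens += result.model.n_obs
        if len(result.morphs) == 0:
            zero_morph.append(result.gesture_action)
        elif len(result.morphs) == 1:
            unimorphic.append(result.gesture_action)
        else:
            polymorphic[result.gesture_action] = result.morphs
    repertoire = MorphRepertoire(
        unimorphic=sorted(unimorphic),
        polymorphic=dict(sorted(polymorphic.items())),
        unspecified=sorted(unspecified_actions),
        zero_morph=sorted(zero_morph),
        n_unassigned=n_unassigned,
        n_analyzed_tokens=n_tokens,
    )
    morph_counts = [len(m) for m in repertoire.polymorphic.values()]
    stats = {
        "n_unimorphic": len(repertoire.unimorphic),
        "n_polymorphic": len(repertoire.polymorphic),
        "n_unspecified": len(repertoire.unspecified),
        "n_zero_morph": len(repertoire.zero_morph),
        "n_polymorphic_morphs": int(sum(morph_counts)),
        "n_units": repertoire.n_units,
        "morphs_per_polymorphic_mean": (
            float(np.mean(morph_counts)) if morph_counts else None
        ),
        "morphs_per_polymorphic_sd": (
            float(np.std(morph_counts, ddof=1)) if len(morph_counts) > 1 else None
        ),
        "morphs_per_polymorphic_range": (
            (int(min(morph_counts)), int(max(morph_counts))) if morph_counts else None
        ),
        "unassigned_fraction": repertoire.unassigned_fraction,
    }
    return repertoire, stats


def analyze_actions(
    tokens: pd.DataFrame,
    vocab: ModifierVocabulary,
    action_min: int = DEFAULT_ACTION_MIN,
    morph_min: int = DEFAULT_MORPH_MIN,
    k_max: int = DEFAULT_K_MAX,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
) -> tuple[list[ActionResult], ExclusionReport, MorphRepertoire, dict]:
    """Full morph-detection pass over a thresholded token table."""
    vectors, report = prepare_lca_inputs(tokens, vocab, action_min=action_min)
    seeds = np.random.SeedSequence(seed).spawn(len(vectors))
    results: list[ActionResult] = []
    for action_seed, (action, action_vectors) in zip(seeds, sorted(vectors.items())):
        model = select_model(
            action_vectors, k_max=k_max, n_restarts=n_restarts, seed=action_seed
        )
        morphs, unassigned = derive_morphs(
            model, morph_min=morph_min, constant_modifiers=action_vectors.constant_modifiers
        )
        results.append(ActionResult(action, model, morphs, unassigned))
    repertoire, stats = summarize_morph_repertoire(results, report.unspecified_actions)
    return results, report, repertoire, stats
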