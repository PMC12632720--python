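"""Component -> functional-network partitions.

A :class:`NetworkPartition` maps each independent component (IC) of a
connectivity matrix to one of the seven canonical resting-state networks
used throughout the package: subcortical (SCN), auditory (AUD),
sensorimotor (SMN), visual (VSN), cognitive control (CCN), default mode
(DMN) and cerebellar (CBN).

The shipped 53-component fixture mirrors the NeuroMark fMRI 1.0 template's
network sizes; smaller synthetic cohorts use :func:`default_partition`,
which allocates components to networks proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

NETWORK_ORDER: tuple[str, ...] = ("SCN", "AUD", "SMN", "VSN", "CCN", "DMN", "CBN")

# Published network sizes of the 53-component template.
_NEUROMARK_SIZES: dict[str, int] = {
    "SCN": 5, "AUD": 2, "SMN": 9, "VSN": 9, "CCN": 17, "DMN": 7, "CBN": 4,
}


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of component indices to network labels.

    Parameters
    ----------
    labels
        One network label per component, index-aligned with the rows and
        columns of the connectivity matrices it will be used to slice.
    """

    labels: tuple[str, ...]
    component_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("partition needs at least one component")
        unknown = set(self.labels) - set(NETWORK_ORDER)
        if unknown:
            raise ValueError(
                f"unknown network labels {sorted(unknown)}; valid: {list(NETWORK_ORDER)}"
            )
        if self.component_ids and len(self.component_ids) != len(self.labels):
            raise ValueError("component_ids must align with labels")

    @property
    def n_components(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = set(self.labels)
        return tuple(n for n in NETWORK_ORDER if n in present)

    def indices(self, network: str) -> list[int]:
        """Component indices belonging to ``network`` (order preserved)."""
        if network not in set(self.labels):
            raise KeyError(
                f"network {network!r} not in partition; valid labels: {list(self.networks)}"
            )
        return [i for i, lab in enumerate(self.labels) if lab == network]


def neuromark53() -> NetworkPartition:
    """The shipped 53-component / 7-network template partition."""
    text = (
        resources.files("dynbag.data").joinpath("neuromark53_partition.tsv").read_text()
    )
    ids, labels = [], []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("component"):
            continue
        cid, net = line.split("\t")
        ids.append(cid)
        labels.append(net)
    part = NetworkPartition(labels=tuple(labels), component_ids=tuple(ids))
    assert part.n_components == 53 and len(part.networks) == 7
    return part


def default_partition(n_components: int) -> NetworkPartition:
    """Partition ``n_components`` components across the 7 networks.

    Components are allocated proportionally to the template's network
    sizes (largest-remainder rounding). Each network receives at least
    one component when ``n_components >= 7`` and at least two when
    ``n_components >= 14`` (so every network contributes at least one
    within-network connectivity feature).
    """
    if n_components == 53:
        return neuromark53()
    if n_components < len(NETWORK_ORDER):
        labels = NETWORK_ORDER[:n_components]
        return NetworkPartition(labels=labels)
    min_size = 2 if n_components >= 2 * len(NETWORK_ORDER) else 1
    total = sum(_NEUROMARK_SIZES.values())
    quotas = {n: n_components * _NEUROMARK_SIZES[n] / total for n in NETWORK_ORDER}
    counts = {n: max(min_size, int(quotas[n])) for n in NETWORK_ORDER}
    # distribute the remainder by largest fractional part
    rem = n_components - sum(counts.values())
    order = sorted(NETWORK_ORDER, key=lambda n: quotas[n] - int(quotas[n]), reverse=True)
    i = 0
    while rem > 0:
        counts[order[i % len(order)]] += 1
        rem -= 1
        i += 1
    while rem < 0:  # over-allocated by the minimum-size floor
        for n in sorted(NETWORK_ORDER, key=lambda n: counts[n], reverse=True):
            if counts[n] > min_size:
                counts[n] -= 1
                rem += 1
                break
    labels: list[str] = []
    for n in NETWORK_ORDER:
        labels.extend([n] * counts[n])
    return NetworkPartition(labels=tuple(labels))
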