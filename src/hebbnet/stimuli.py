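"""Word and pseudoword stimulus generation.

A "word" is a triplet of sparse binary activation patterns over the primary
areas: an auditory pattern (A1) and an articulatory pattern (M1_i) always,
plus a semantic-grounding pattern in V1 for object words or in M1_L for
action words.  Each pattern is a fixed set of randomly chosen cells
(19 of 625, about 3%, at full scale).

Pseudowords are novel auditory-only patterns built by recombining the
trained words' A1 patterns: the grid is tiled into 5x5 sub-squares and each
pseudoword takes, at every tile position, the content of that position from
one source word (two tiles from each word, the odd tile from a uniformly
drawn word), so pseudowords are made entirely of familiar parts in familiar
positions but form no trained whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .params import ConfigError

__all__ = ["StimulusSet", "make_word_patterns", "make_pseudowords", "stimulus_drive"]

AUDITORY = "A1"
ARTICULATORY = "M1_i"
VISUAL = "V1"
MOTOR = "M1_L"


@dataclass
class StimulusSet:
    """Word patterns, derived pseudoword patterns and category labels."""

    grid: int
    words: list[dict[str, np.ndarray]]  # area name -> flat cell indices
    categories: list[str]  # 'object' | 'action', parallel to words
    pseudowords: list[np.ndarray] = field(default_factory=list)  # A1-only
    pseudoword_sources: list[np.ndarray] = field(default_factory=list)

    @property
    def n_words(self) -> int:
        return len(self.words)

    def word_a1(self, i: int) -> np.ndarray:
        return self.words[i][AUDITORY]

    def grounding_area(self, i: int) -> str:
        return VISUAL if self.categories[i] == "object" else MOTOR


def make_word_patterns(
    rng: np.random.Generator | int | None,
    n_words: int = 12,
    cells_per_pattern: int = 19,
    grid: int = 25,
) -> StimulusSet:
    """Draw the word stimulus set: independent patterns per primary area.

    The first half of the words is object-related (grounded in V1), the
    second half action-related (grounded in M1_L).
    """
    if cells_per_pattern > grid * grid:
        raise ConfigError(
            f"cells_per_pattern ({cells_per_pattern}) exceeds area size ({grid * grid})"
        )
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n_object = (n_words + 1) // 2
    words: list[dict[str, np.ndarray]] = []
    categories: list[str] = []
    for i in range(n_words):
        category = "object" if i < n_object else "action"
        grounding = VISUAL if category == "object" else MOTOR
        pattern = {
            area: np.sort(rng.choice(grid * grid, size=cells_per_pattern, replace=False))
            for area in (AUDITORY, ARTICULATORY, grounding)
        }
        words.append(pattern)
        categories.append(category)
    return StimulusSet(grid=grid, words=words, categories=categories)


def _tile_of(cells: np.ndarray, grid: int, s: int) -> np.ndarray:
    r, c = cells // grid, cells % grid
    tiles_per_row = -(-grid // s)  # ceil
    return (r // s) * tiles_per_row + (c // s)


def make_pseudowords(
    stimuli: StimulusSet,
    rng: np.random.Generator | int | None,
    subsquare: int = 5,
) -> StimulusSet:
    """Derive one pseudoword per word by sub-square recombination (in place).

    The grid is tiled into ``subsquare`` x ``subsquare`` blocks (clipped at
    the boundary).  For each pseudoword every tile position is assigned a
    source word; the pseudoword inherits exactly the source word's A1 cells
    inside that tile, preserving spatial position.  With 25 tiles and 12
    words the composition is two tiles per word plus one uniformly drawn
    extra; other word/tile counts fall back to proportional sourcing with
    the remainder drawn uniformly without replacement.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    g, s = stimuli.grid, subsquare
    n_words = stimuli.n_words
    tiles_per_row = -(-g // s)
    n_tiles = tiles_per_row * tiles_per_row
    base, rem = divmod(n_tiles, n_words)
    if base == 0:
        warnings.warn(
            f"more words ({n_words}) than tiles ({n_tiles}); sources drawn uniformly",
            stacklevel=2,
        )

    word_tiles = [_tile_of(stimuli.word_a1(i), g, s) for i in range(n_words)]
    stimuli.pseudowords = []
    stimuli.pseudoword_sources = []
    for _ in range(n_words):
        sources = np.repeat(np.arange(n_words), base)
        if rem:
            extra = rng.choice(n_words, size=rem, replace=rem > n_words)
            sources = np.concatenate([sources, extra])
        rng.shuffle(sources)
        cells: list[np.ndarray] = []
        for tile, src in enumerate(sources):
            take = stimuli.word_a1(src)[word_tiles[src] == tile]
            cells.append(take)
        stimuli.pseudowords.append(np.sort(np.concatenate(cells)).astype(np.int64))
        stimuli.pseudoword_sources.append(sources)
    return stimuli


def stimulus_drive(
    connectome: Connectome,
    pattern: dict[str, np.ndarray],
    amplitude: float,
) -> np.ndarray:
    """External drive vector: ``amplitude`` at each pattern cell, 0 elsewhere.

    ``pattern`` maps area names to within-area flat cell indices.  The drive
    enters the membrane equation inside the k1-rescaled net input, so only
    the nominated cells of the nominated areas are affected.
    """
    drive = np.zeros(connectome.n_exc)
    for area, cells in pattern.items():
        if area not in connectome.areas:
            raise ConfigError(f"stimulus references unknown area {area!r}")
        drive[connectome.area_slice(area)][cells] = amplitude
    return drive
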