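"""Regenerate the 50-row test fixture (tests/data/mini_survey.csv).

The fixture is a plain generator draw with a small city/community frame so
fixed-effect designs stay full rank at n=50.
"""

from pathlib import Path

from healthineq import GeneratorConfig, generate_survey, write_survey

HERE = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = GeneratorConfig(n_respondents=50, seed=42, n_cities=5,
                          n_communities=15)
    df, truth = generate_survey(cfg)
    out = HERE / "tests" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_survey(df, truth, cfg, out / "mini_survey.csv")
    print(f"wrote {len(df)} rows to {out / 'mini_survey.csv'}")


if __name__ == "__main__":
    main()
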