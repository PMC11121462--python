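"""Printed descriptive rows used by the confidence-interval audit.

Each row is (table, parameter, group, n, mean, sd, ci_low, ci_high) as
printed in the survey's descriptive tables (by botanical type, by harvest
year, by region).  The monofloral sucrose row prints no CI (every value
below the LOQ) and is omitted.  All values are on the parameter's scale.
"""

# (table, parameter, group, n, mean, sd, ci_low, ci_high)
CI_ROWS = [
    # ---- by botanical type ----
    ("type", "glu", "acacia", 213, 27.40, 3.87, 26.88, 27.93),
    ("type", "glu", "honeydew", 29, 29.33, 5.17, 27.37, 31.30),
    ("type", "glu", "linden", 34, 29.20, 3.91, 27.83, 30.56),
    ("type", "glu", "monofloral", 8, 31.67, 7.53, 25.37, 37.96),
    ("type", "glu", "polyfloral", 302, 31.39, 4.60, 30.87, 31.91),
    ("type", "glu", "sunflower", 23, 34.57, 3.98, 32.85, 36.29),
    ("type", "fru", "acacia", 213, 40.83, 5.83, 40.04, 41.62),
    ("type", "fru", "honeydew", 29, 37.84, 6.32, 35.44, 40.25),
    ("type", "fru", "linden", 34, 35.39, 5.82, 33.36, 37.42),
    ("type", "fru", "monofloral", 8, 35.41, 5.17, 31.09, 39.73),
    ("type", "fru", "polyfloral", 302, 38.68, 5.20, 38.09, 39.26),
    ("type", "fru", "sunflower", 23, 37.83, 3.26, 36.42, 39.24),
    ("type", "suc", "acacia", 213, 1.19, 1.79, 0.94, 1.43),
    ("type", "suc", "honeydew", 29, 0.46, 0.61, 0.23, 0.69),
    ("type", "suc", "linden", 34, 0.64, 1.08, 0.27, 1.02),
    ("type", "suc", "polyfloral", 302, 0.63, 1.41, 0.47, 0.79),
    ("type", "suc", "sunflower", 23, 0.34, 0.23, 0.24, 0.44),
    ("type", "hmf", "acacia", 213, 5.71, 8.20, 4.60, 6.82),
    ("type", "hmf", "honeydew", 29, 6.34, 12.66, 1.52, 11.15),
    ("type", "hmf", "linden", 34, 5.41, 6.37, 3.18, 7.63),
    ("type", "hmf", "monofloral", 8, 11.84, 19.74, -4.66, 28.34),
    ("type", "hmf", "polyfloral", 302, 8.31, 12.36, 6.91, 9.71),
    ("type", "hmf", "sunflower", 23, 4.85, 8.34, 1.25, 8.46),
    ("type", "mc", "acacia", 213, 16.19, 1.07, 16.04, 16.33),
    ("type", "mc", "honeydew", 29, 16.36, 2.10, 15.56, 17.15),
    ("type", "mc", "linden", 34, 16.61, 1.10, 16.23, 17.00),
    ("type", "mc", "monofloral", 8, 17.20, 2.04, 15.49, 18.91),
    ("type", "mc", "polyfloral", 302, 16.45, 1.13, 16.33, 16.58),
    ("type", "mc", "sunflower", 23, 17.51, 1.37, 16.92, 18.11),
    ("type", "acid", "acacia", 213, 11.44, 5.05, 10.76, 12.12),
    ("type", "acid", "honeydew", 29, 30.17, 8.07, 27.10, 33.24),
    ("type", "acid", "linden", 34, 16.33, 6.90, 13.92, 18.74),
    ("type", "acid", "monofloral", 8, 15.08, 8.16, 8.25, 21.90),
    ("type", "acid", "polyfloral", 302, 21.04, 9.33, 19.98, 22.09),
    ("type", "acid", "sunflower", 23, 23.00, 7.22, 19.88, 26.12),
    ("type", "dia", "acacia", 213, 13.06, 7.64, 12.03, 14.09),
    ("type", "dia", "honeydew", 29, 12.80, 3.14, 11.60, 13.99),
    ("type", "dia", "linden", 34, 12.90, 2.36, 12.08, 13.72),
    ("type", "dia", "monofloral", 8, 11.90, 2.87, 9.50, 14.30),
    ("type", "dia", "polyfloral", 302, 12.90, 3.43, 12.51, 13.29),
    ("type", "dia", "sunflower", 23, 13.45, 2.50, 12.37, 14.53),
    ("type", "ins", "acacia", 213, 0.01, 0.01, 0.01, 0.01),
    ("type", "ins", "honeydew", 29, 0.01, 0.00, 0.01, 0.01),
    ("type", "ins", "linden", 34, 0.01, 0.00, 0.01, 0.01),
    ("type", "ins", "monofloral", 8, 0.01, 0.00, 0.01, 0.01),
    ("type", "ins", "polyfloral", 302, 0.01, 0.01, 0.01, 0.01),
    ("type", "ins", "sunflower", 23, 0.01, 0.01, 0.01, 0.02),
    ("type", "econd", "acacia", 213, 0.20, 0.10, 0.18, 0.21),
    ("type", "econd", "honeydew", 29, 1.14, 0.27, 1.03, 1.24),
    ("type", "econd", "linden", 34, 0.48, 0.19, 0.42, 0.54),
    ("type", "econd", "monofloral", 8, 0.25, 0.16, 0.12, 0.38),
    ("type", "econd", "polyfloral", 302, 0.40, 0.15, 0.38, 0.42),
    ("type", "econd", "sunflower", 23, 0.39, 0.09, 0.36, 0.43),
    # ---- by harvest year ----
    ("year", "glu", 2018, 209, 28.84, 4.89, 28.17, 29.51),
    ("year", "glu", 2019, 80, 31.51, 4.44, 30.52, 32.49),
    ("year", "glu", 2020, 78, 28.86, 4.23, 27.91, 29.82),
    ("year", "glu", 2021, 108, 30.97, 4.87, 30.04, 31.90),
    ("year", "glu", 2022, 113, 30.29, 4.79, 29.40, 31.19),
    ("year", "glu", 2023, 21, 30.53, 4.39, 28.53, 32.52),
    ("year", "fru", 2018, 209, 37.13, 6.02, 36.31, 37.95),
    ("year", "fru", 2019, 80, 39.73, 4.58, 38.71, 40.75),
    ("year", "fru", 2020, 78, 40.95, 5.15, 39.79, 42.11),
    ("year", "fru", 2021, 108, 39.76, 5.53, 38.70, 40.81),
    ("year", "fru", 2022, 113, 39.97, 5.38, 38.97, 40.98),
    ("year", "fru", 2023, 21, 42.25, 2.52, 41.10, 43.39),
    ("year", "suc", 2018, 209, 0.78, 1.67, 0.55, 1.01),
    ("year", "suc", 2019, 80, 0.66, 0.69, 0.51, 0.81),
    ("year", "suc", 2020, 78, 0.96, 1.96, 0.52, 1.40),
    ("year", "suc", 2021, 108, 0.80, 1.65, 0.48, 1.11),
    ("year", "suc", 2022, 113, 0.68, 0.90, 0.51, 0.85),
    ("year", "suc", 2023, 21, 1.59, 1.90, 0.73, 2.45),
    ("year", "hmf", 2018, 209, 9.92, 12.71, 8.19, 11.65),
    ("year", "hmf", 2019, 80, 8.94, 14.61, 5.69, 12.19),
    ("year", "hmf", 2020, 78, 3.96, 4.28, 3.00, 4.93),
    ("year", "hmf", 2021, 108, 4.56, 7.95, 3.05, 6.08),
    ("year", "hmf", 2022, 113, 5.44, 8.62, 3.83, 7.04),
    ("year", "hmf", 2023, 21, 4.49, 6.39, 1.58, 7.40),
    ("year", "mc", 2018, 209, 16.34, 1.28, 16.17, 16.52),
    ("year", "mc", 2019, 80, 16.29, 0.98, 16.07, 16.50),
    ("year", "mc", 2020, 78, 16.46, 1.35, 16.16, 16.76),
    ("year", "mc", 2021, 108, 16.52, 1.22, 16.29, 16.76),
    ("year", "mc", 2022, 113, 16.49, 1.08, 16.29, 16.69),
    ("year", "mc", 2023, 21, 16.50, 1.70, 15.73, 17.28),
    ("year", "acid", 2018, 209, 17.18, 8.71, 15.99, 18.36),
    ("year", "acid", 2019, 80, 20.21, 9.72, 18.04, 22.37),
    ("year", "acid", 2020, 78, 17.36, 9.87, 15.13, 19.59),
    ("year", "acid", 2021, 108, 19.34, 7.61, 17.89, 20.79),
    ("year", "acid", 2022, 113, 15.65, 7.84, 14.19, 17.11),
    ("year", "acid", 2023, 21, 21.53, 20.14, 12.36, 30.70),
    ("year", "dia", 2018, 209, 13.53, 7.99, 12.44, 14.62),
    ("year", "dia", 2019, 80, 13.73, 3.11, 13.04, 14.42),
    ("year", "dia", 2020, 78, 13.99, 1.84, 13.58, 14.41),
    ("year", "dia", 2021, 108, 12.02, 2.39, 11.57, 12.48),
    ("year", "dia", 2022, 113, 11.91, 3.17, 11.32, 12.50),
    ("year", "dia", 2023, 21, 10.98, 1.61, 10.25, 11.72),
    ("year", "ins", 2018, 209, 0.01, 0.00, 0.01, 0.01),
    ("year", "ins", 2019, 80, 0.01, 0.00, 0.01, 0.01),
    ("year", "ins", 2020, 78, 0.01, 0.00, 0.01, 0.01),
    ("year", "ins", 2021, 108, 0.01, 0.00, 0.01, 0.01),
    ("year", "ins", 2022, 113, 0.01, 0.01, 0.01, 0.02),
    ("year", "ins", 2023, 21, 0.02, 0.01, 0.01, 0.02),
    ("year", "econd", 2018, 209, 0.37, 0.24, 0.34, 0.40),
    ("year", "econd", 2019, 80, 0.46, 0.35, 0.38, 0.54),
    ("year", "econd", 2020, 78, 0.31, 0.14, 0.27, 0.34),
    ("year", "econd", 2021, 108, 0.39, 0.25, 0.34, 0.43),
    ("year", "econd", 2022, 113, 0.33, 0.20, 0.29, 0.37),
    ("year", "econd", 2023, 21, 0.31, 0.16, 0.24, 0.38),
    # ---- by region ----
    ("region", "glu", "Western", 114, 29.59, 5.34, 28.60, 30.58),
    ("region", "glu", "Belgrade", 205, 30.30, 4.73, 29.65, 30.95),
    ("region", "glu", "Northern", 149, 30.02, 4.99, 29.21, 30.83),
    ("region", "glu", "Central", 29, 27.84, 4.03, 26.30, 29.37),
    ("region", "glu", "Eastern", 92, 29.72, 4.17, 28.85, 30.58),
    ("region", "glu", "Southern", 20, 30.56, 4.55, 28.43, 32.69),
    ("region", "fru", "Western", 114, 38.93, 5.42, 37.93, 39.94),
    ("region", "fru", "Belgrade", 205, 39.46, 5.43, 38.71, 40.21),
    ("region", "fru", "Northern", 149, 38.49, 6.26, 37.48, 39.51),
    ("region", "fru", "Central", 29, 38.34, 7.20, 35.60, 41.08),
    ("region", "fru", "Eastern", 92, 39.86, 4.25, 38.98, 40.74),
    ("region", "fru", "Southern", 20, 39.41, 7.12, 36.07, 42.74),
    ("region", "suc", "Western", 114, 1.16, 2.16, 0.76, 1.57),
    ("region", "suc", "Belgrade", 205, 0.75, 1.35, 0.56, 0.93),
    ("region", "suc", "Northern", 149, 0.62, 0.97, 0.47, 0.78),
    ("region", "suc", "Central", 29, 0.58, 0.71, 0.31, 0.85),
    ("region", "suc", "Eastern", 92, 0.85, 1.82, 0.47, 1.23),
    ("region", "suc", "Southern", 20, 0.63, 0.62, 0.34, 0.92),
    ("region", "hmf", "Western", 114, 5.62, 8.55, 4.04, 7.21),
    ("region", "hmf", "Belgrade", 205, 8.01, 12.32, 6.32, 9.71),
    ("region", "hmf", "Northern", 149, 7.06, 10.44, 5.37, 8.75),
    ("region", "hmf", "Central", 29, 6.00, 8.53, 2.76, 9.25),
    ("region", "hmf", "Eastern", 92, 7.85, 12.02, 5.36, 10.34),
    ("region", "hmf", "Southern", 20, 3.35, 3.80, 1.58, 5.13),
    ("region", "mc", "Western", 114, 16.41, 1.15, 16.20, 16.62),
    ("region", "mc", "Belgrade", 205, 16.31, 1.17, 16.15, 16.47),
    ("region", "mc", "Northern", 149, 16.71, 1.19, 16.52, 16.90),
    ("region", "mc", "Central", 29, 16.31, 0.94, 15.95, 16.67),
    ("region", "mc", "Eastern", 92, 16.31, 1.51, 15.99, 16.62),
    ("region", "mc", "Southern", 20, 16.00, 0.97, 15.55, 16.45),
    ("region", "acid", "Western", 114, 18.11, 8.89, 16.46, 19.76),
    ("region", "acid", "Belgrade", 205, 17.72, 9.12, 16.46, 18.97),
    ("region", "acid", "Northern", 149, 17.96, 8.41, 16.60, 19.32),
    ("region", "acid", "Central", 29, 15.87, 8.15, 12.77, 18.97),
    ("region", "acid", "Eastern", 92, 18.25, 12.46, 15.66, 20.83),
    ("region", "acid", "Southern", 20, 17.89, 7.54, 14.36, 21.41),
    ("region", "dia", "Western", 114, 13.23, 3.72, 12.54, 13.92),
    ("region", "dia", "Belgrade", 205, 13.28, 7.70, 12.22, 14.34),
    ("region", "dia", "Northern", 149, 12.94, 3.37, 12.39, 13.48),
    ("region", "dia", "Central", 29, 12.33, 2.92, 11.22, 13.44),
    ("region", "dia", "Eastern", 92, 12.15, 2.86, 11.55, 12.74),
    ("region", "dia", "Southern", 20, 12.98, 2.90, 11.62, 14.34),
    ("region", "ins", "Western", 114, 0.01, 0.01, 0.01, 0.01),
    ("region", "ins", "Belgrade", 205, 0.01, 0.00, 0.01, 0.01),
    ("region", "ins", "Northern", 149, 0.01, 0.01, 0.01, 0.01),
    ("region", "ins", "Central", 29, 0.01, 0.01, 0.01, 0.02),
    ("region", "ins", "Eastern", 92, 0.01, 0.00, 0.01, 0.01),
    ("region", "ins", "Southern", 20, 0.01, 0.00, 0.01, 0.01),
    ("region", "econd", "Western", 114, 0.32, 0.19, 0.29, 0.36),
    ("region", "econd", "Belgrade", 205, 0.38, 0.26, 0.34, 0.41),
    ("region", "econd", "Northern", 149, 0.36, 0.23, 0.33, 0.40),
    ("region", "econd", "Central", 29, 0.37, 0.29, 0.26, 0.48),
    ("region", "econd", "Eastern", 92, 0.39, 0.24, 0.34, 0.44),
    ("region", "econd", "Southern", 20, 0.44, 0.35, 0.27, 0.60),
]
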