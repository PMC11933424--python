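You are an expert pharmacometrician reviewing tables from the scientific
literature on drug studies. Your task is to assign exactly one category to the
table shown below: PK, DEMOGRAPHICS, or OTHER.

Category definitions and criteria:

PK — the table reports in vivo pharmacokinetic parameter estimates.
  Include: clearance (CL, CL/F), volume of distribution (V, Vd, Vss), area
  under the concentration-time curve (AUC), maximum concentration (Cmax),
  time to maximum concentration (Tmax), half-life (t1/2), absorption or
  elimination rate constants (ka, ke), bioavailability (F), mean residence
  time (MRT), and similar derived parameters with values and units.
  Exclude: tables that contain only raw concentration measurements without
  any derived PK parameter, and purely in vitro kinetic constants.

DEMOGRAPHICS — the table reports study population characteristics.
  Include: age, body weight, height, BMI, sex distribution, ethnicity,
  baseline clinical characteristics of the enrolled subjects.
  Exclude: tables whose population columns are incidental to PK parameter
  reporting (those are PK if parameters dominate).

OTHER — anything else.
  Include: adverse events and safety summaries, pharmacodynamic or clinical
  endpoints, in vitro assay results, stability tests, study design schedules,
  and tables of individual or mean drug concentration measurements that do
  NOT report derived PK parameters.

Think through the decision step by step:
1. Read the caption and footer: do they mention pharmacokinetic parameters,
   population characteristics, or something else?
2. Scan the header row and first column: are the row/column labels PK
   parameter names with units, demographic variables, or other quantities?
3. Check the body cells: are the values parameter estimates (often value
   plus or minus a standard deviation), subject characteristics, or raw
   measurements such as concentration-time points?
4. Apply the exclusion rules: concentration-only tables and pharmacodynamic
   endpoints are OTHER even when they look pharmacokinetic.
5. Decide on the single best category.

Table ID: {table_id}

Caption:
{caption}

Table:
{table_markdown}

Footer:
{footer}

Explain your reasoning briefly, then give your final answer on the last line
in exactly this format:
ANSWER: <PK|DEMOGRAPHICS|OTHER>
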