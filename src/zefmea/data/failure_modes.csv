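id,category,description
A1,Sample-related,Insufficient sample amount or quality
A2,Sample-related,Inappropriate sample preparation techniques
A3,Sample-related,Contamination during sample collection or handling
A4,Sample-related,Volatile material or unstable material affecting metabolite extraction or stability
A5,Sample-related,The freshness of the plant material affects metabolite yield and quality
A6,Sample-related,"Selecting appropriate plant tissues for sampling, such as roots, leaves, or flowers, is imperative for ensuring the validity & reliability of research findings"
A7,Extraction method,Inadequate extraction solvent or concentration
A8,Extraction method,"Suboptimal extraction conditions (time, temperature, pH, etc.)"
A9,Extraction method,"Inefficient extraction technique (solid-liquid extraction, liquid-liquid extraction)"
A10,Extraction method,Incompatibility between the extraction method and target metabolites
A11,Extraction method,Inadequate choice of solvent
A12,"Instrumentation, Calibration, and Reference Standards",Inaccurate or malfunctioning equipment
A13,"Instrumentation, Calibration, and Reference Standards",Poor calibration or incorrect settings
A14,"Instrumentation, Calibration, and Reference Standards",Contamination in the analytical system
A15,"Instrumentation, Calibration, and Reference Standards",Instrumental and device errors affecting the accuracy and precision of measurements
A16,Analytical method-related issues,"Inappropriate choice of analytical technique (chromatography, spectroscopy)"
A17,Analytical method-related issues,Lack of specificity or sensitivity in the method
A18,Analytical method-related issues,Inadequate separation or detection of target metabolites
A19,Analytical method-related issues,Matrix interference affecting the analysis
A20,Analytical method-related issues,Lack of reference standards for metabolite identification and quantification
A21,Operator-related issues and data analysis,Lack of training or expertise in extraction and analysis techniques
A22,Operator-related issues and data analysis,Inconsistent or improper execution of the extraction method
A23,Operator-related issues and data analysis,"Human error during sample handling analysis, or data processing"
A24,Operator-related issues and data analysis,Inadequate statistical analysis or data interpretation
A25,Biological and environmental factors,"Variability in metabolite content due to plant species, genotype, or developmental stage"
A26,Biological and environmental factors,Presence of interfering compounds or endogenous substances
A27,Biological and environmental factors,Seasonal variations affecting metabolite composition
A28,Biological and environmental factors,Impact of environmental stressors on metabolite extraction
A29,Biological and environmental factors,Plant fertility or nutrient status influencing metabolite production & accumulation
A30,Biological and environmental factors,"Allocations of diverse compounds across distinct plant components (roots, leaves, flowers)"
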