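{
  "schema_version": "1.0",
  "image_id": "synthetic-seed20",
  "image_path": null,
  "rater_id": null,
  "timestamp": null,
  "jugulum": [
    400.0,
    80.0
  ],
  "nipple_left": [
    240.0,
    244.0
  ],
  "nipple_right": [
    560.0,
    244.0
  ],
  "border_left": [
    [
      343.60860531691327,
      232.0
    ],
    [
      344.28045060359034,
      246.3870442594387
    ],
    [
      342.69229542571827,
      260.85606359037513
    ],
    [
      338.7852545544836,
      274.9892600108111
    ],
    [
      332.5696471410864,
      288.33186204164303
    ],
    [
      324.23342853567055,
      300.4712179453119
    ],
    [
      314.152731781707,
      311.15273178170696
    ],
    [
      302.7777397970226,
      320.329670217309
    ],
    [
      290.4751556124659,
      328.0857880785808
    ],
    [
      277.4449792682021,
      334.4712446039383
    ],
    [
      263.769165036643,
      339.367985608086
    ],
    [
      249.54612182232663,
      342.4887646561384
    ],
    [
      235.0,
      343.5213076833483
    ],
    [
      220.4757021821072,
      342.32299488470426
    ],
    [
      206.32162634162336,
      339.0291475715066
    ],
    [
      192.75348213198586,
      333.9921163999971
    ],
    [
      179.81473108626557,
      327.5836895879394
    ],
    [
      167.48240831925295,
      319.99063859148185
    ],
    [
      155.8565395948126,
      311.1434604051874
    ],
    [
      145.2974622072415,
      300.8311781385863
    ],
    [
      136.3972442736556,
      288.92832756144384
    ],
    [
      129.78175032953862,
      275.58282602266354
    ],
    [
      125.86322650728067,
      261.2431103219125
    ],
    [
      124.70487824930619,
      246.52062825018479
    ],
    [
      126.078141699341,
      232.0
    ],
    [
      127.54392329167528,
      217.85313912040624
    ],
    [
      131.0964382631817,
      204.15912454190223
    ],
    [
      136.66985233246766,
      191.27031924595897
    ],
    [
      144.15218592161432,
      179.548990086555
    ],
    [
      153.27449344078497,
      169.28981321086275
    ],
    [
      163.60877032359917,
      160.60877032359926
    ],
    [
      174.69094653919333,
      153.40371131784008
    ],
    [
      186.18049674926468,
      147.44213996945257
    ],
    [
      197.9414871070892,
      142.53283557255645
    ],
    [
      209.99241668773993,
      138.67042850413378
    ],
    [
      222.36867214479392,
      136.05553949463877
    ],
    [
      234.99999999999997,
      134.97564622346582
    ],
    [
      247.68800696922975,
      135.6250188811875
    ],
    [
      260.19179833949204,
      137.98292866298624
    ],
    [
      272.3491775849698,
      141.83110893088445
    ],
    [
      284.1328924566982,
      146.89933394218116
    ],
    [
      295.5864420754272,
      153.04221143712908
    ],
    [
      306.6724053052575,
      160.32759469474252
    ],
    [
      317.1371602235686,
      168.97394024450378
    ],
    [
      326.49649763483336,
      179.17447246062093
    ],
    [
      334.16978351821643,
      190.92253068915096
    ],
    [
      339.6851968538001,
      203.94968604353105
    ],
    [
      342.82307680397156,
      217.80482264119954
    ]
  ],
  "border_right": [
    [
      456.39139468308673,
      232.0
    ],
    [
      455.71954939640966,
      246.3870442594387
    ],
    [
      457.30770457428173,
      260.85606359037513
    ],
    [
      461.2147454455164,
      274.9892600108111
    ],
    [
      467.4303528589136,
      288.33186204164303
    ],
    [
      475.76657146432945,
      300.4712179453119
    ],
    [
      485.847268218293,
      311.15273178170696
    ],
    [
      497.2222602029774,
      320.329670217309
    ],
    [
      509.5248443875341,
      328.0857880785808
    ],
    [
      522.5550207317979,
      334.4712446039383
    ],
    [
      536.230834963357,
      339.367985608086
    ],
    [
      550.4538781776733,
      342.4887646561384
    ],
    [
      565.0,
      343.5213076833483
    ],
    [
      579.5242978178928,
      342.32299488470426
    ],
    [
      593.6783736583766,
      339.0291475715066
    ],
    [
      607.2465178680142,
      333.9921163999971
    ],
    [
      620.1852689137345,
      327.5836895879394
    ],
    [
      632.517591680747,
      319.99063859148185
    ],
    [
      644.1434604051874,
      311.1434604051874
    ],
    [
      654.7025377927584,
      300.8311781385863
    ],
    [
      663.6027557263444,
      288.92832756144384
    ],
    [
      670.2182496704613,
      275.58282602266354
    ],
    [
      674.1367734927194,
      261.2431103219125
    ],
    [
      675.2951217506939,
      246.52062825018479
    ],
    [
      673.921858300659,
      232.0
    ],
    [
      672.4560767083248,
      217.85313912040624
    ],
    [
      668.9035617368183,
      204.15912454190223
    ],
    [
      663.3301476675324,
      191.27031924595897
    ],
    [
      655.8478140783857,
      179.548990086555
    ],
    [
      646.7255065592151,
      169.28981321086275
    ],
    [
      636.3912296764008,
      160.60877032359926
    ],
    [
      625.3090534608067,
      153.40371131784008
    ],
    [
      613.8195032507354,
      147.44213996945257
    ],
    [
      602.0585128929108,
      142.53283557255645
    ],
    [
      590.0075833122601,
      138.67042850413378
    ],
    [
      577.6313278552061,
      136.05553949463877
    ],
    [
      565.0,
      134.97564622346582
    ],
    [
      552.3119930307703,
      135.6250188811875
    ],
    [
      539.808201660508,
      137.98292866298624
    ],
    [
      527.6508224150302,
      141.83110893088445
    ],
    [
      515.8671075433018,
      146.89933394218116
    ],
    [
      504.4135579245728,
      153.04221143712908
    ],
    [
      493.3275946947425,
      160.32759469474252
    ],
    [
      482.8628397764314,
      168.97394024450378
    ],
    [
      473.50350236516664,
      179.17447246062093
    ],
    [
      465.83021648178357,
      190.92253068915096
    ],
    [
      460.3148031461999,
      203.94968604353105
    ],
    [
      457.17692319602844,
      217.80482264119954
    ]
  ]
}
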