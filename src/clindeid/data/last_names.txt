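González
Muñoz
Rojas
Díaz
Pérez
Soto
Contreras
Silva
Martínez
Sepúlveda
Morales
Rodríguez
López
Fuentes
Hernández
Torres
Araya
Flores
Espinoza
Valenzuela
Castillo
Tapia
Reyes
Gutiérrez
Castro
Pizarro
Álvarez
Vásquez
Sánchez
Fernández
Ramírez
Carrasco
Gómez
Cortés
Herrera
Núñez
Jara
Vergara
Rivera
Figueroa
Riquelme
García
Miranda
Bravo
Vera
Molina
Vega
Sandoval
Campos
Orellana
Cárdenas
Olivares
Alarcón
Ortiz
Garrido
Salazar
Gallardo
Ruiz
Escobar
Guzmán
Saavedra
Henríquez
Navarro
Parra
Vargas
Méndez
Salinas
Zúñiga
Romero
Aguilera
Lagos
Leiva
Medina
Maldonado
Bustos
Cáceres
Yáñez
Palma
Aravena
Venegas
Toro
Ortega
Peña
Godoy
Aguirre
Navarrete
Bustamante
Paredes
Moreno
Velásquez
Acuña
Donoso
Farías
Ponce
Ibarra
Córdova
Cifuentes
Arriagada
Quezada
Villarroel
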